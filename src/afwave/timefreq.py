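"""Continuous wavelet transform with the Mexican-hat wavelet and scalograms.

The CWT of a signal x is T(a, b) = (1/sqrt(a)) * sum_t x(t) psi((t - b)/a),
evaluated here on the sample grid (t, b in samples, a dimensionless).  Each
scale a maps to a pseudo-frequency F = Fc * fs / a, with Fc the center
frequency of the mother wavelet; for the Mexican hat the toolbox convention
Fc = 0.25 is used, which is within 1% of the analytic energy-peak location
sqrt(2.5)/(2*pi) of the scalogram magnitude.  Coefficient magnitude |T| feeds
the rendered image (energy-density view); signed coefficients remain
available on the Scalogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import fftconvolve

from .digitize import GrayImage
from .errors import ConfigError, InputError
from .trace import ECGTrace

__all__ = [
    "MEXH_CENTER_FREQUENCY",
    "WaveletSpec",
    "ScaleGrid",
    "Scalogram",
    "mexh",
    "scale_to_frequency",
    "frequency_to_scale",
    "cwt",
    "render_scalogram",
]

# Discrete-wavelet-toolbox convention for the Mexican hat center frequency
# (dominant-FFT-peak estimate of the sampled wavelet).
MEXH_CENTER_FREQUENCY = 0.25

# The Mexican hat decays as exp(-t^2/2): beyond |t| = 8 it is < 1e-12.
_SUPPORT_RADIUS = 8.0


def mexh(t) -> np.ndarray:
    """Mexican-hat wavelet: (2 / (sqrt(3) * pi**(1/4))) * exp(-t^2/2) * (1 - t^2).

    The negative-normalized second derivative of a Gaussian; zero-mean
    (admissible) and even, with zeros at t = +/-1.
    """
    t = np.asarray(t, dtype=float)
    return (2.0 / (np.sqrt(3.0) * np.pi**0.25)) * np.exp(-0.5 * t**2) * (1.0 - t**2)


def scale_to_frequency(a, Fc: float = MEXH_CENTER_FREQUENCY, fs: float = 1.0):
    """Pseudo-frequency in Hz of scale a: F = Fc * fs / a."""
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ConfigError("scales must be positive")
    return Fc * fs / a


def frequency_to_scale(F, Fc: float = MEXH_CENTER_FREQUENCY, fs: float = 1.0):
    """Exact inverse of scale_to_frequency: a = Fc * fs / F."""
    F = np.asarray(F, dtype=float)
    if np.any(F <= 0):
        raise ConfigError("frequencies must be positive")
    return Fc * fs / F


@dataclass(frozen=True)
class WaveletSpec:
    """Mother-wavelet choice.  Only the Mexican hat ships; its shape matches
    the QRS complex, which is why it is the standard pick for ECG scalograms."""

    name: str = "mexh"
    center_frequency: float = MEXH_CENTER_FREQUENCY

    def validate(self) -> None:
        if self.name != "mexh":
            raise ConfigError(f"unsupported wavelet {self.name!r}; only 'mexh' ships")
        if self.center_frequency <= 0:
            raise ConfigError("center_frequency must be positive")


@dataclass(frozen=True)
class ScaleGrid:
    """Scales in ascending order (= descending pseudo-frequency) plus the
    pseudo-frequency of each scale at the working sampling rate."""

    scales: np.ndarray
    pseudo_frequencies: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        s = np.asarray(self.scales, dtype=float)
        if s.size == 0:
            raise ConfigError("empty scale grid")
        if np.any(s <= 0):
            raise ConfigError("scales must be positive")
        if np.any(np.diff(s) <= 0):
            raise ConfigError("scales must be strictly increasing")
        object.__setattr__(self, "scales", s)
        object.__setattr__(
            self, "pseudo_frequencies", np.asarray(self.pseudo_frequencies, dtype=float)
        )

    def __len__(self) -> int:
        return self.scales.size

    @classmethod
    def log_spaced(
        cls,
        fs: float,
        n_scales: int = 64,
        fmin: float = 1.0,
        fmax: float = 50.0,
        Fc: float = MEXH_CENTER_FREQUENCY,
    ) -> "ScaleGrid":
        """Log-spaced pseudo-frequencies from fmax down to fmin.

        The default 1-50 Hz span covers P/QRS/T morphology and the 4-10 Hz
        fibrillatory band of AF.
        """
        if not 0 < fmin < fmax:
            raise ConfigError("need 0 < fmin < fmax")
        if fmax > fs / 2:
            raise ConfigError("fmax above Nyquist")
        freqs = np.geomspace(fmax, fmin, n_scales)  # descending
        scales = frequency_to_scale(freqs, Fc, fs)  # ascending
        return cls(scales=scales, pseudo_frequencies=freqs, fs=fs)


@dataclass
class Scalogram:
    """CWT coefficients over (scale, time).

    ``signed`` holds T(a, b); ``coefficients`` is the magnitude |T| that the
    image rendering consumes.  Row order follows the scale grid: row 0 is the
    smallest scale, i.e. the highest pseudo-frequency.
    """

    signed: np.ndarray
    scale_grid: ScaleGrid
    time_axis: np.ndarray
    normalization: str = "none"
    _magnitude: np.ndarray | None = field(default=None, repr=False)

    @property
    def coefficients(self) -> np.ndarray:
        if self._magnitude is None:
            self._magnitude = np.abs(self.signed)
        return self._magnitude

    @property
    def shape(self) -> tuple[int, int]:
        return self.signed.shape


def cwt(
    segment: ECGTrace | np.ndarray,
    grid: ScaleGrid,
    wavelet: WaveletSpec | None = None,
) -> Scalogram:
    """Continuous wavelet transform of one segment on the given scale grid.

    Per scale a, the kernel psi(k/a) is sampled on |k| <= 8a (where the
    Mexican hat has decayed below 1e-12) and correlated with the
    symmetrically padded signal; the evenness of the Mexican hat makes
    convolution and correlation identical.  Each row is scaled by 1/sqrt(a).
    """
    wavelet = wavelet or WaveletSpec()
    wavelet.validate()
    if isinstance(segment, ECGTrace):
        x = segment.samples
        fs = segment.fs
    else:
        x = np.asarray(segment, dtype=float)
        fs = grid.fs
    if x.ndim != 1 or x.size < 3:
        raise InputError("segment must be a 1-D signal with at least 3 samples")

    n = x.size
    coeffs = np.empty((len(grid), n))
    for i, a in enumerate(grid.scales):
        radius = int(np.ceil(_SUPPORT_RADIUS * a))
        k = np.arange(-radius, radius + 1)
        psi = mexh(k / a)
        pad = min(radius, n - 1)
        xp = np.pad(x, pad, mode="symmetric")
        row = fftconvolve(xp, psi, mode="same")[pad : pad + n]
        coeffs[i] = row / np.sqrt(a)

    time_axis = np.arange(n) / fs
    return Scalogram(signed=coeffs, scale_grid=grid, time_axis=time_axis)


def render_scalogram(s: Scalogram, out_size: tuple[int, int] = (224, 224)) -> GrayImage:
    """Min-max normalize |T| to [0, 1] and bilinearly resize to ``out_size``.

    Row 0 of the output is the highest pseudo-frequency.  A constant
    coefficient matrix (no dynamic range) renders as an all-0.5 image.
    """
    rows, cols = out_size
    if rows < 1 or cols < 1:
        raise ConfigError("out_size must be positive")
    mag = s.coefficients
    lo, hi = float(mag.min()), float(mag.max())
    if hi > lo:
        norm = (mag - lo) / (hi - lo)
    else:
        norm = np.full_like(mag, 0.5)

    if norm.shape == (rows, cols):
        return GrayImage(norm.copy())
    # Bilinear resize with corner alignment: the output corner samples
    # coincide with the input corners.
    src_r = np.arange(norm.shape[0], dtype=float)
    src_c = np.arange(norm.shape[1], dtype=float)
    interp = RegularGridInterpolator((src_r, src_c), norm, method="linear")
    rr = np.linspace(0, norm.shape[0] - 1, rows)
    cc = np.linspace(0, norm.shape[1] - 1, cols)
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    out = interp(np.stack([grid_r.ravel(), grid_c.ravel()], axis=1)).reshape(rows, cols)
    return GrayImage(np.clip(out, 0.0, 1.0))
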