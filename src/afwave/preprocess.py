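"""Trace denoising, resampling, and fixed-length segmentation.

The denoising chain is the standard three-filter ambulatory-ECG recipe:
a high-pass to remove baseline wander, a notch at the mains frequency to
remove power-line interference, and a low-pass against high-frequency noise.
All filters are applied forward-backward (zero phase) so QRS peaks are not
shifted in time.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .errors import ConfigError, InputError
from .trace import ECGTrace

__all__ = ["FilterSpec", "SegmentationSpec", "denoise", "resample", "segment"]


@dataclass(frozen=True)
class FilterSpec:
    """Cutoffs of the three-filter denoising chain (Hz).

    Defaults: 0.5 Hz high-pass (baseline wander sits below ~0.5 Hz),
    45 Hz low-pass (below the 50/60 Hz mains), 60 Hz notch with Q = 30.
    ``notch_hz=None`` skips the notch (e.g. when the low-pass already
    excludes the mains, or at low sampling rates).
    """

    highpass_hz: float = 0.5
    lowpass_hz: float = 45.0
    notch_hz: float | None = 60.0
    notch_q: float = 30.0
    order: int = 4

    def validate(self, fs: float) -> None:
        nyq = fs / 2
        if not 0 < self.highpass_hz < self.lowpass_hz:
            raise ConfigError("need 0 < highpass_hz < lowpass_hz")
        if self.lowpass_hz >= nyq:
            raise ConfigError(f"lowpass_hz {self.lowpass_hz} >= Nyquist {nyq}")
        if self.notch_hz is not None and not 0 < self.notch_hz < nyq:
            raise ConfigError(f"notch_hz {self.notch_hz} outside (0, Nyquist)")

    @classmethod
    def default_for_fs(cls, fs: float) -> "FilterSpec":
        """A valid default chain for the given rate: at 300 Hz the standard
        0.5/45/notch-60 chain; at low rates the low-pass shrinks to 0.8*Nyquist
        and an unobservable mains notch is dropped."""
        nyq = fs / 2
        lowpass = min(45.0, 0.8 * nyq)
        notch: float | None = 60.0 if 60.0 < nyq else None
        return cls(lowpass_hz=lowpass, notch_hz=notch)


@dataclass(frozen=True)
class SegmentationSpec:
    """Fixed-length windowing: ~5 s windows are the working segment length."""

    window_s: float = 5.0
    overlap_s: float = 0.0
    pad_policy: str = "drop"  # or "zero-pad"

    def validate(self) -> None:
        if self.window_s <= 0:
            raise ConfigError("window_s must be positive")
        if not 0 <= self.overlap_s < self.window_s:
            raise ConfigError("need 0 <= overlap_s < window_s")
        if self.pad_policy not in ("drop", "zero-pad"):
            raise ConfigError(f"unknown pad_policy {self.pad_policy!r}")


def denoise(trace: ECGTrace, spec: FilterSpec | None = None) -> ECGTrace:
    """Apply the zero-phase high-pass / notch / low-pass chain."""
    spec = spec or FilterSpec.default_for_fs(trace.fs)
    spec.validate(trace.fs)
    # filtfilt needs a few filter lengths of signal.
    if len(trace) < 3 * (2 * spec.order + 1):
        raise InputError("trace shorter than the filter transient")
    x = trace.samples
    sos_hp = signal.butter(spec.order, spec.highpass_hz, "highpass", fs=trace.fs, output="sos")
    x = signal.sosfiltfilt(sos_hp, x)
    if spec.notch_hz is not None:
        b, a = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=trace.fs)
        x = signal.filtfilt(b, a, x)
    sos_lp = signal.butter(spec.order, spec.lowpass_hz, "lowpass", fs=trace.fs, output="sos")
    x = signal.sosfiltfilt(sos_lp, x)
    return trace.with_samples(x)


def resample(trace: ECGTrace, target_fs: float) -> ECGTrace:
    """Band-limited (polyphase) resampling to ``target_fs``.

    Reconciles sources recorded at different rates (e.g. 300 Hz public
    records versus 60 Hz printed strips) before a shared pipeline.
    """
    if target_fs <= 0:
        raise ConfigError("target_fs must be positive")
    if target_fs == trace.fs:
        return trace.with_samples(trace.samples.copy())
    frac = Fraction(target_fs / trace.fs).limit_denominator(1000)
    y = signal.resample_poly(trace.samples, frac.numerator, frac.denominator)
    return trace.with_samples(y, fs=target_fs)


def segment(trace: ECGTrace, spec: SegmentationSpec | None = None) -> list[ECGTrace]:
    """Cut a trace into fixed-length windows that inherit the parent label.

    With ``pad_policy="drop"`` the tail shorter than a window is discarded
    (an input shorter than one window yields an empty list); with
    ``"zero-pad"`` the final partial window is zero-padded to full length.
    """
    spec = spec or SegmentationSpec()
    spec.validate()
    if len(trace) == 0:
        raise InputError("empty trace")
    win = int(round(spec.window_s * trace.fs))
    step = win - int(round(spec.overlap_s * trace.fs))
    if win < 1 or step < 1:
        raise ConfigError("window/overlap resolve to less than one sample")

    segments: list[ECGTrace] = []
    x = trace.samples
    start = 0
    while start + win <= len(x):
        segments.append(_child(trace, x[start : start + win], len(segments)))
        start += step
    if spec.pad_policy == "zero-pad" and (start < len(x) or not segments):
        tail = x[start:]
        if tail.size > 0:
            padded = np.zeros(win)
            padded[: tail.size] = tail
            segments.append(_child(trace, padded, len(segments)))
    return segments


def _child(trace: ECGTrace, samples: np.ndarray, k: int) -> ECGTrace:
    child = trace.with_samples(samples.copy())
    child.source_id = f"{trace.source_id}#{k}" if trace.source_id else f"#{k}"
    return child
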