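"""Synthetic single-lead ECG generator and strip renderer.

The generator produces labeled normal / atrial-fibrillation traces built from
Gaussian-bump beat morphology.  It is deliberately not a dynamical heart
model: it expresses exactly the two ECG features that distinguish AF on a
single lead — absent P waves replaced by a low-amplitude fibrillatory
oscillation, and irregular R-R intervals — plus additive measurement noise.
The strip renderer draws a trace on a gridded raster the way clinical ECG
paper printouts look, so the digitizer can be exercised end to end without
any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .digitize import GrayImage
from .errors import ConfigError, InputError
from .trace import ECGTrace

__all__ = [
    "EcgGenSpec",
    "StripRenderSpec",
    "normal_spec",
    "af_spec",
    "generate_ecg",
    "make_dataset",
    "render_strip",
]

# Beat morphology: (amplitude, center offset from R in s, Gaussian sd in s).
# P/QRS/T bumps; amplitudes relative to the R wave.
_P_WAVE = (0.15, -0.17, 0.022)
_QRS = ((-0.10, -0.025, 0.009), (1.00, 0.0, 0.011), (-0.18, 0.025, 0.009))
_T_WAVE = (0.30, 0.22, 0.050)

# Template half-extent: beyond ~0.32 s from the R peak all bumps are negligible.
_TEMPLATE_EXTENT_S = 0.35


@dataclass(frozen=True)
class EcgGenSpec:
    """Parameters of one synthetic recording.

    rr_cv is the coefficient of variation of the R-R intervals; p_wave toggles
    atrial depolarization bumps; fwave_amp/fwave_hz describe the fibrillatory
    baseline oscillation (relative to the R amplitude of 1).
    """

    fs: float = 300.0
    duration_s: float = 30.0
    heart_rate_bpm: float = 70.0
    rr_cv: float = 0.03
    p_wave: bool = True
    fwave_amp: float = 0.0
    fwave_hz: float = 7.0
    noise_sd: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if self.rr_cv < 0:
            raise ConfigError("rr_cv must be non-negative")
        if not 0 < self.fwave_hz < self.fs / 2:
            raise ConfigError("fwave_hz must lie in (0, fs/2)")
        mean_rr = 60.0 / self.heart_rate_bpm
        if mean_rr < _TEMPLATE_EXTENT_S:
            raise ConfigError(
                f"heart rate {self.heart_rate_bpm} bpm gives RR {mean_rr:.3f} s, "
                f"shorter than the beat template ({_TEMPLATE_EXTENT_S} s)"
            )


def normal_spec(**overrides) -> EcgGenSpec:
    """Default normal-sinus-rhythm conditions: 70 bpm, nearly regular RR,
    P wave present, no fibrillatory component."""
    return replace(EcgGenSpec(), **overrides)


def af_spec(**overrides) -> EcgGenSpec:
    """Default AF conditions: 95 bpm, strongly irregular RR (CV 0.15), absent
    P wave, 7 Hz fibrillatory oscillation at 0.1 relative amplitude."""
    base = EcgGenSpec(
        heart_rate_bpm=95.0,
        rr_cv=0.15,
        p_wave=False,
        fwave_amp=0.10,
        fwave_hz=7.0,
    )
    return replace(base, **overrides)


def _gauss(t: np.ndarray, amp: float, mu: float, sd: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - mu) / sd) ** 2)


def generate_ecg(spec: EcgGenSpec) -> ECGTrace:
    """Generate one labeled trace from the spec.

    Beats are placed at R-R intervals drawn from a normal distribution with
    the requested mean and CV (floored so beats never collapse onto each
    other); each beat adds P (optional), Q, R, S and T Gaussian bumps.  AF
    traces add a sinusoidal fibrillatory wave.  All randomness flows from
    ``spec.seed``.  The true beat times are stored in ``meta['beat_times_s']``
    so oracle statistics (e.g. RR-interval CV) need no QRS detector.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs

    mean_rr = 60.0 / spec.heart_rate_bpm
    # Draw more intervals than can fit, then trim.
    n_draw = int(np.ceil(spec.duration_s / mean_rr)) + 8
    rr = rng.normal(mean_rr, spec.rr_cv * mean_rr, size=n_draw)
    rr = np.maximum(rr, _TEMPLATE_EXTENT_S)
    beats = np.cumsum(np.concatenate([[0.4 * mean_rr], rr]))
    beats = beats[beats < spec.duration_s]

    x = np.zeros(n)
    for tb in beats:
        lo = max(0, int((tb - _TEMPLATE_EXTENT_S) * spec.fs))
        hi = min(n, int((tb + _TEMPLATE_EXTENT_S) * spec.fs) + 1)
        tt = t[lo:hi] - tb
        seg = np.zeros_like(tt)
        if spec.p_wave:
            seg += _gauss(tt, *_P_WAVE)
        for bump in _QRS:
            seg += _gauss(tt, *bump)
        seg += _gauss(tt, *_T_WAVE)
        x[lo:hi] += seg

    if spec.fwave_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += spec.fwave_amp * np.sin(2 * np.pi * spec.fwave_hz * t + phase)
    if spec.noise_sd > 0:
        x += rng.normal(0, spec.noise_sd, size=n)

    label = "normal" if spec.p_wave else "af"
    return ECGTrace(
        samples=x,
        fs=spec.fs,
        label=label,
        meta={"beat_times_s": beats, "gen_spec": spec},
    )


def make_dataset(
    n_normal: int,
    n_af: int,
    *,
    segments_per_subject: int = 5,
    normal: EcgGenSpec | None = None,
    af: EcgGenSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> list[ECGTrace]:
    """Generate a labeled trace collection with subject structure.

    Subjects contribute ``segments_per_subject`` consecutive traces each (the
    last subject of a class may contribute fewer), so an inter-patient
    train/test split is meaningful.  Class counts are exactly as requested —
    e.g. (700, 100) reproduces the ~7:1 normal-to-AF imbalance of public AF
    corpora.  With ``out_dir`` set, traces are written as CSV plus a JSON
    manifest of labels and subject ids.
    """
    if n_normal < 0 or n_af < 0:
        raise InputError("class counts must be non-negative")
    normal = normal or normal_spec(duration_s=5.0)
    af = af or af_spec(duration_s=5.0)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_normal + n_af) % (2**31)

    traces: list[ECGTrace] = []
    idx = 0
    for label, count, base in (("normal", n_normal, normal), ("af", n_af, af)):
        for i in range(count):
            subject = f"{label[0]}{i // segments_per_subject:04d}"
            spec = replace(base, seed=int(child_seeds[idx]))
            tr = generate_ecg(spec)
            tr.source_id = f"{label}_{i:05d}"
            tr.meta["subject"] = subject
            traces.append(tr)
            idx += 1

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = []
        for tr in traces:
            fname = f"{tr.source_id}.csv"
            tr.to_csv(out_dir / fname)
            manifest.append(
                {"file": fname, "label": tr.label, "subject": tr.meta["subject"], "fs": tr.fs}
            )
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return traces


@dataclass(frozen=True)
class StripRenderSpec:
    """How a trace is drawn on ECG-paper-style raster.

    Background intensity is 0, grid lines are drawn lighter than the trace
    (grid_intensity < 1), and the waveform polyline is drawn at the darkest
    intensity 1, matching the shade ordering of scanned clinical strips.
    """

    grid_spacing_px: int = 20
    grid_intensity: float = 0.5
    line_width_px: int = 1
    image_height_px: int = 300
    margin_px: int = 12
    px_per_sample: int = 2
    max_width_px: int = 6000

    def validate(self) -> None:
        if not 0 < self.grid_intensity < 1:
            raise ConfigError("grid_intensity must lie in (0, 1) (trace intensity is 1)")
        if self.image_height_px < 2 * self.margin_px + 2:
            raise ConfigError("image too short for the configured margin")


def render_strip(trace: ECGTrace, spec: StripRenderSpec | None = None) -> GrayImage:
    """Draw a trace as a gridded grayscale strip.

    Each sample occupies a dedicated pixel column at its (rounded) row, and
    the ``px_per_sample - 1`` columns in between carry connector strokes
    spanning the rows of the two neighboring samples, keeping the polyline
    connected through steep QRS deflections.  A connector column's mean
    occupied row is the midpoint of its neighbors, so a column-mean digitizer
    recovers a linearly interpolated version of the waveform.
    """
    spec = spec or StripRenderSpec()
    spec.validate()
    n = len(trace)
    if n < 1:
        raise InputError("empty trace")
    w = spec.px_per_sample * (n - 1) + 1
    if w > spec.max_width_px:
        raise ConfigError(f"trace needs {w} px but the drawable width is {spec.max_width_px} px")
    h = spec.image_height_px
    img = np.zeros((h, w))

    # Grid first, trace on top (darkest wins).
    img[:: spec.grid_spacing_px, :] = spec.grid_intensity
    img[:, :: spec.grid_spacing_px] = spec.grid_intensity

    x = trace.samples
    lo, hi = float(x.min()), float(x.max())
    span = hi - lo if hi > lo else 1.0
    # Row 0 is the image top = largest voltage.
    usable = h - 1 - 2 * spec.margin_px
    rows = (h - 1 - spec.margin_px) - (x - lo) / span * usable

    half = max(0, (spec.line_width_px - 1) // 2)
    pps = spec.px_per_sample

    def stroke(col: int, top: float, bot: float) -> None:
        a = max(0, int(round(top)) - half)
        b = min(h - 1, int(round(bot)) + half)
        img[a : b + 1, col] = 1.0

    for m in range(n):
        r = rows[m]
        stroke(pps * m, r, r)
        if m + 1 < n:
            r_next = rows[m + 1]
            lo_r, hi_r = min(r, r_next), max(r, r_next)
            for k in range(1, pps):
                stroke(pps * m + k, lo_r, hi_r)
    return GrayImage(img)
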