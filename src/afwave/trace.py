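"""Single-lead ECG time series container and CSV I/O.

The trace is the lingua franca of the pipeline: the strip digitizer produces
one, the denoiser and segmenter map traces to traces, and the wavelet
transform consumes one.  Amplitudes are in arbitrary units after digitization
(z-scored by default) and in millivolts only when an explicit calibration
factor was supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputError

__all__ = ["ECGTrace"]

_VALID_LABELS = (None, "normal", "af")


@dataclass
class ECGTrace:
    """A uniformly sampled single-lead ECG voltage series.

    Parameters
    ----------
    samples : ndarray
        Voltage samples, finite, length >= 1.
    fs : float
        Sampling rate in Hz, > 0.
    label : {None, "normal", "af"}
        Optional rhythm annotation for the whole recording.
    source_id : str
        Free-text provenance (file name, subject id, ...).
    meta : dict
        Auxiliary information (e.g. known beat times for synthetic traces,
        digitization reports).
    """

    samples: np.ndarray
    fs: float
    label: str | None = None
    source_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise InputError("trace must be a non-empty 1-D sample array")
        if not np.all(np.isfinite(self.samples)):
            raise InputError("trace contains non-finite samples")
        if not self.fs > 0:
            raise InputError(f"sampling rate must be positive, got {self.fs}")
        if self.label not in _VALID_LABELS:
            raise InputError(f"label must be one of {_VALID_LABELS}, got {self.label!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Record duration in seconds (n samples / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs

    @property
    def y(self) -> int:
        """Binary class for the classifier: 1 = AF, 0 = normal."""
        if self.label is None:
            raise InputError("trace has no label")
        return int(self.label == "af")

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "ECGTrace":
        """Return a copy with new samples (and optionally rate), keeping metadata."""
        return ECGTrace(
            samples=np.asarray(samples, dtype=float),
            fs=self.fs if fs is None else fs,
            label=self.label,
            source_id=self.source_id,
            meta=dict(self.meta),
        )

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> None:
        """Write the trace as two-column CSV (time_s, amplitude)."""
        data = np.column_stack([self.times, self.samples])
        np.savetxt(path, data, delimiter=",", header="time_s,amplitude", comments="")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        fs: float | None = None,
        label: str | None = None,
    ) -> "ECGTrace":
        """Read a two-column CSV.  If ``fs`` is omitted it is inferred from the
        median spacing of the time column."""
        path = Path(path)
        if not path.exists():
            raise InputError(f"no such file: {path}")
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if data.shape[1] < 2:
            raise InputError(f"{path}: expected two columns (time_s, amplitude)")
        t, x = data[:, 0], data[:, 1]
        if fs is None:
            dt = np.median(np.diff(t)) if t.size > 1 else None
            if not dt or dt <= 0:
                raise InputError(f"{path}: cannot infer sampling rate")
            fs = 1.0 / dt
        return cls(samples=x, fs=float(fs), label=label, source_id=path.name)
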