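"""Exception hierarchy for the afwave package."""


class AfwaveError(Exception):
    """Base class for all afwave errors."""


class InputError(AfwaveError):
    """Raised for unreadable, empty, or malformed input data."""


class ConfigError(AfwaveError):
    """Raised for invalid parameter combinations (e.g. cutoff above Nyquist)."""


class MetricError(AfwaveError):
    """Raised when a metric is undefined for the given labels (e.g. one class)."""


class TrainingError(AfwaveError):
    """Raised when optimization diverges (non-finite loss)."""
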