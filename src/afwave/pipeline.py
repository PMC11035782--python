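"""End-to-end glue: traces -> denoised segments -> scalogram image dataset.

This is the data path of the full classifier: denoise each recording,
cut it into fixed-length windows, wavelet-transform each window, and render
the magnitude scalogram as a fixed-size grayscale image.  Labels and subject
ids ride along so training can split inter-patiently.
"""

from __future__ import annotations

import numpy as np

from .mbtrain import LabeledDataset
from .preprocess import FilterSpec, SegmentationSpec, denoise, segment
from .timefreq import ScaleGrid, WaveletSpec, cwt, render_scalogram
from .trace import ECGTrace

__all__ = ["traces_to_dataset", "trace_to_images"]


def trace_to_images(
    trace: ECGTrace,
    grid: ScaleGrid,
    seg_spec: SegmentationSpec,
    image_size: tuple[int, int],
    filter_spec: FilterSpec | None = None,
    apply_denoise: bool = True,
    wavelet: WaveletSpec | None = None,
) -> list[np.ndarray]:
    """Denoise, window, and scalogram-render one recording."""
    tr = denoise(trace, filter_spec) if apply_denoise else trace
    images = []
    for seg in segment(tr, seg_spec):
        s = cwt(seg, grid, wavelet)
        images.append(render_scalogram(s, image_size).pixels.astype(np.float32))
    return images


def traces_to_dataset(
    traces: list[ECGTrace],
    n_scales: int = 64,
    fmin: float = 1.0,
    fmax: float = 50.0,
    image_size: tuple[int, int] = (224, 224),
    window_s: float = 5.0,
    overlap_s: float = 0.0,
    filter_spec: FilterSpec | None = None,
    apply_denoise: bool = True,
) -> LabeledDataset:
    """Build the labeled scalogram-image dataset for a trace collection.

    All traces must share one sampling rate (resample first if not); each
    window inherits its recording's label and subject id.
    """
    if not traces:
        raise ValueError("no traces given")
    fs = traces[0].fs
    grid = ScaleGrid.log_spaced(fs=fs, n_scales=n_scales, fmin=fmin, fmax=fmax)
    seg_spec = SegmentationSpec(window_s=window_s, overlap_s=overlap_s)

    images, labels, subjects = [], [], []
    for tr in traces:
        if tr.fs != fs:
            raise ValueError(f"mixed sampling rates ({tr.fs} vs {fs}); resample first")
        subj = tr.meta.get("subject", tr.source_id or "anon")
        for img in trace_to_images(
            tr, grid, seg_spec, image_size, filter_spec, apply_denoise
        ):
            images.append(img)
            labels.append(tr.y)
            subjects.append(subj)

    return LabeledDataset(
        labels=np.array(labels),
        images=np.stack(images)[:, None],
        subjects=np.array(subjects),
    )
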