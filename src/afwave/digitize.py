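"""ECG strip digitization: raster image -> binary trace mask -> time series.

Scanned or printed ECG strips show the waveform in the darkest ink over a
lighter grid on a light background.  Working in an inverted intensity
convention (background 0, grid strictly between 0 and 1, trace 1), the
digitizer thresholds away the grid, collects the surviving "black" pixel
coordinates, and reconstructs one amplitude sample per pixel column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ConfigError, InputError
from .trace import ECGTrace

__all__ = [
    "GrayImage",
    "PixelSet",
    "rasterize_document",
    "remove_grid",
    "extract_pixel_set",
    "pixels_to_trace",
    "digitize_strip",
]

_RASTER_SUFFIXES = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg", ".gif"}


@dataclass
class GrayImage:
    """2-D intensity raster, values in [0, 1], 1 = darkest.

    ``pixels[n, m]`` is the intensity h(m, n) at column m (the time axis,
    increasing rightward) and row n (the amplitude axis, increasing
    downward).
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InputError("image must be a non-empty 2-D array")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise InputError("intensities must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def h(self, m: int, n: int) -> float:
        """Intensity at column m, row n."""
        return float(self.pixels[n, m])

    def save_png(self, path: str | Path) -> None:
        """Write as 8-bit grayscale PNG (re-inverting so 1 -> black ink)."""
        arr = np.round((1.0 - self.pixels) * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(path)


@dataclass
class PixelSet:
    """Set of (m, n) coordinates flagged as signal pixels."""

    points: set = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.points)

    def to_array(self) -> np.ndarray:
        """(k, 2) int array of sorted (m, n) pairs."""
        if not self.points:
            return np.empty((0, 2), dtype=int)
        return np.array(sorted(self.points), dtype=int)


def rasterize_document(
    document: str | Path,
    dpi: int = 150,
    crop: tuple[int, int, int, int] | None = None,
) -> GrayImage:
    """Load a raster strip document as a [0, 1] gray image, 1 = darkest.

    Accepts PNG/TIFF/BMP/JPEG rasters.  PDFs must be exported to a raster
    image (at the desired dpi) before digitization; ``dpi`` is kept in the
    signature as the rendering-resolution contract for such exports.
    ``crop`` is (col_min, col_max, row_min, row_max) and selects a sub-strip,
    e.g. one row of a multi-row page.
    """
    path = Path(document)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if path.suffix.lower() == ".pdf":
        raise InputError(
            "PDF input is not supported directly; export the page as a PNG/TIFF "
            f"raster at {dpi} dpi and digitize that"
        )
    if path.suffix.lower() not in _RASTER_SUFFIXES:
        raise InputError(f"unsupported document format: {path.suffix}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"), dtype=float)
    except Exception as exc:  # pillow raises many concrete types
        raise InputError(f"unreadable image {path}: {exc}") from exc
    if arr.size == 0:
        raise InputError(f"zero-area page: {path}")
    pixels = 1.0 - arr / 255.0  # invert: ink (dark) -> 1, background -> 0
    if crop is not None:
        c0, c1, r0, r1 = crop
        pixels = pixels[r0:r1, c0:c1]
        if pixels.size == 0:
            raise InputError("crop box selects an empty region")
    return GrayImage(pixels)


def remove_grid(image: GrayImage, trace_threshold: float = 0.9) -> GrayImage:
    """Binarize: keep only near-ink pixels, zero the lighter grid/background.

    Grid lines print strictly lighter than the waveform (0 < h < 1 versus
    h = 1), so thresholding at 1 removes them exactly on ideal rasters; the
    default 0.9 tolerates anti-aliasing.  Idempotent, and raising the
    threshold never adds pixels.
    """
    if not 0 < trace_threshold <= 1:
        raise ConfigError("trace_threshold must lie in (0, 1]")
    binary = (image.pixels >= trace_threshold).astype(float)
    return GrayImage(binary)


def extract_pixel_set(binary: GrayImage) -> PixelSet:
    """Collect S = {(m, n) | h(m, n) = 1} from a binary image."""
    vals = np.unique(binary.pixels)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise InputError("extract_pixel_set requires a binary image")
    rows, cols = np.nonzero(binary.pixels == 1.0)
    return PixelSet(points=set(zip(cols.tolist(), rows.tolist())))


def pixels_to_trace(
    points: PixelSet,
    image_height: int,
    fs: float,
    calibration: float | str = "normalize",
) -> ECGTrace:
    """Reconstruct the ECG series from signal pixel coordinates.

    One sample per occupied column; a column with several rows (a steep
    stroke) contributes the mean of its rows.  Row 0 is the image top and the
    largest voltage, so amplitude = (image_height - 1 - mean_row).  Interior
    columns with no pixels are linearly interpolated from their neighbors;
    leading/trailing empty columns are trimmed.  ``calibration`` is either
    "normalize" (z-score the result) or an amplitude-per-pixel factor.
    """
    if fs <= 0:
        raise ConfigError("fs must be positive")
    pts = points.to_array()
    if pts.shape[0] == 0:
        raise InputError("no signal found: pixel set is empty")

    cols = pts[:, 0]
    rows = pts[:, 1].astype(float)
    c_min, c_max = int(cols.min()), int(cols.max())
    # Mean occupied row per column (columns are already sorted in pts).
    sums = np.bincount(cols - c_min, weights=rows, minlength=c_max - c_min + 1)
    counts = np.bincount(cols - c_min, minlength=c_max - c_min + 1)
    occupied = counts > 0
    mean_row = np.full(c_max - c_min + 1, np.nan)
    mean_row[occupied] = sums[occupied] / counts[occupied]

    n_interp = int(np.sum(~occupied))
    if n_interp:
        xi = np.arange(mean_row.size)
        mean_row[~occupied] = np.interp(xi[~occupied], xi[occupied], mean_row[occupied])

    amplitude = (image_height - 1) - mean_row
    if calibration == "normalize":
        sd = amplitude.std()
        amplitude = (amplitude - amplitude.mean()) / sd if sd > 0 else amplitude * 0.0
    elif isinstance(calibration, (int, float)):
        amplitude = amplitude * float(calibration)
    else:
        raise ConfigError(f"unknown calibration {calibration!r}")

    return ECGTrace(
        samples=amplitude,
        fs=fs,
        meta={
            "digitize_report": {
                "n_pixels": int(pts.shape[0]),
                "n_columns": int(mean_row.size),
                "n_columns_interpolated": n_interp,
                "first_column": c_min,
            }
        },
    )


def digitize_strip(
    document: str | Path,
    fs: float,
    dpi: int = 150,
    trace_threshold: float = 0.9,
    crop: tuple[int, int, int, int] | None = None,
    calibration: float | str = "normalize",
) -> ECGTrace:
    """Full strip pipeline: rasterize -> remove grid -> extract -> trace."""
    image = rasterize_document(document, dpi=dpi, crop=crop)
    binary = remove_grid(image, trace_threshold)
    points = extract_pixel_set(binary)
    return pixels_to_trace(points, image.height, fs, calibration)
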