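"""Trichome density from tape-peel micrographs.

A longitudinal strip of trichomes is lifted from the fruit surface with
black tape and imaged under a stereo microscope.  The 8-bit grayscale image
is thresholded to a binary mask (trichomes bright on the dark tape), and
percent pixel coverage is measured inside three equidistant rectangular
subsections, each 1.75 mm (along the strip) x 7.00 mm (across) = 12.25 mm^2,
positioned near the calyx end, the centre, and the pedicel end of the strip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ROI_HEIGHT_MM",
    "ROI_WIDTH_MM",
    "ROI_AREA_MM2",
    "DEFAULT_THRESHOLD",
    "DEFAULT_PIXEL_AREA_MM2",
    "Micrograph",
    "ROISpec",
    "TrichomeDensityResult",
    "binarize",
    "place_rois",
    "roi_geometry",
    "percent_coverage",
    "quantify",
    "read_micrograph",
    "write_micrograph",
]

# ROI extent along / across the strip's long axis, and the resulting area.
ROI_HEIGHT_MM = 1.75
ROI_WIDTH_MM = 7.00
ROI_AREA_MM2 = ROI_HEIGHT_MM * ROI_WIDTH_MM

# Midpoint of the 8-bit range: exact for synthetic two-level images, where
# foreground and background intensities are rendered well apart.
DEFAULT_THRESHOLD = 128

# Pixel area of the reference stereo-microscope setup (mm^2 per pixel).
DEFAULT_PIXEL_AREA_MM2 = 4.43e-6

# Centres of the three ROIs as fractions of the strip's long axis: equal
# gaps between consecutive ROIs and between the outer ROIs and the ends.
ROI_CENTER_FRACTIONS = (1 / 6, 1 / 2, 5 / 6)
ROI_POSITIONS = ("calyx", "centre", "pedicel")


@dataclass
class Micrograph:
    """8-bit grayscale tape-strip image with physical calibration.

    ``mm_per_pixel`` is the linear calibration; ``truth_mask`` holds the
    rendered ground-truth foreground for synthetic images only.
    """

    pixels: np.ndarray
    mm_per_pixel: float
    truth_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("micrograph must be a non-empty 2-D intensity array")
        if self.pixels.dtype != np.uint8:
            self.pixels = np.clip(np.asarray(self.pixels, dtype=float), 0, 255).astype(np.uint8)
        if not self.mm_per_pixel > 0:
            raise ValueError("mm_per_pixel must be positive")


@dataclass(frozen=True)
class ROISpec:
    """Rectangular subsection in pixel coordinates (0-based, origin top-left)."""

    position: str
    top: int
    left: int
    height_px: int
    width_px: int

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.top, self.top + self.height_px),
            slice(self.left, self.left + self.width_px),
        )

    @property
    def n_pixels(self) -> int:
        return self.height_px * self.width_px


@dataclass(frozen=True)
class TrichomeDensityResult:
    calyx_pct: float
    centre_pct: float
    pedicel_pct: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.calyx_pct, self.centre_pct, self.pedicel_pct)


def binarize(img: Micrograph, threshold: int | str = DEFAULT_THRESHOLD,
             invert: bool = False) -> np.ndarray:
    """Threshold the micrograph: pixels >= threshold are trichome (1), else 0.

    ``threshold`` may be ``"otsu"`` to pick the threshold from the intensity
    histogram (for real micrographs); synthetic two-level images use the fixed
    midpoint default.  ``invert`` flips intensities first, for images with
    dark trichomes on a bright background.
    """
    pixels = img.pixels
    if invert:
        pixels = (255 - pixels.astype(np.int16)).astype(np.uint8)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(pixels))
        return (pixels > thr).astype(np.uint8)
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    return (pixels >= threshold).astype(np.uint8)


def roi_geometry(shape: tuple[int, int], mm_per_pixel: float) -> list[ROISpec]:
    """Compute the three ROI rectangles for an image of the given shape.

    The strip's long axis is the image's larger dimension; ROIs extend
    1.75 mm along it and 7.00 mm across it, centred on the short axis, with
    centres at fractions 1/6, 1/2 and 5/6 of the long axis.
    """
    nrow, ncol = shape
    long_is_rows = nrow >= ncol
    long_len, short_len = (nrow, ncol) if long_is_rows else (ncol, nrow)

    along_px = round(ROI_HEIGHT_MM / mm_per_pixel)
    across_px = round(ROI_WIDTH_MM / mm_per_pixel)
    min_long = int(np.ceil(3 * along_px))
    if across_px > short_len or min_long > long_len:
        need = (min_long, across_px) if long_is_rows else (across_px, min_long)
        raise ValueError(
            f"image {shape} too small for three {ROI_HEIGHT_MM} x {ROI_WIDTH_MM} mm "
            f"ROIs at {mm_per_pixel} mm/px; minimum size {need[0]} x {need[1]} pixels"
        )

    short_start = (short_len - across_px) // 2
    rois = []
    for position, frac in zip(ROI_POSITIONS, ROI_CENTER_FRACTIONS):
        center = frac * long_len
        long_start = int(round(center - along_px / 2))
        long_start = min(max(long_start, 0), long_len - along_px)
        if long_is_rows:
            roi = ROISpec(position, long_start, short_start, along_px, across_px)
        else:
            roi = ROISpec(position, short_start, long_start, across_px, along_px)
        rois.append(roi)
    return rois


def place_rois(img: Micrograph) -> list[ROISpec]:
    """Place the calyx, centre and pedicel ROIs on a micrograph."""
    return roi_geometry(img.pixels.shape, img.mm_per_pixel)


def percent_coverage(mask: np.ndarray, roi: ROISpec) -> float:
    """Percent of set pixels inside the ROI."""
    mask = np.asarray(mask)
    rs, cs = roi.slices()
    if rs.stop > mask.shape[0] or cs.stop > mask.shape[1] or roi.top < 0 or roi.left < 0:
        raise ValueError(f"ROI {roi.position!r} exceeds mask bounds {mask.shape}")
    sub = mask[rs, cs]
    return 100.0 * float(np.count_nonzero(sub)) / sub.size


def quantify(img: Micrograph, threshold: int | str = DEFAULT_THRESHOLD,
             invert: bool = False) -> TrichomeDensityResult:
    """Binarize, place the three ROIs, and measure percent coverage in each."""
    mask = binarize(img, threshold=threshold, invert=invert)
    rois = place_rois(img)
    pct = {roi.position: percent_coverage(mask, roi) for roi in rois}
    return TrichomeDensityResult(pct["calyx"], pct["centre"], pct["pedicel"])


def read_micrograph(path, mm_per_pixel: float) -> Micrograph:
    """Read a PNG/TIFF micrograph; multi-channel images are converted by luminance."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        warnings.warn(f"{path}: multi-channel image converted to grayscale by luminance")
        arr = arr[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    return Micrograph(pixels=arr, mm_per_pixel=mm_per_pixel)


def write_micrograph(path, img: Micrograph) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, img.pixels)
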