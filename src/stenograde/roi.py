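"""Region-of-interest extraction around the straightened vessel centerline.

The ROI is a rectangle spanning the centerline column +/- 20 (41 columns: the
40-pixel span plus the centerline column itself), whose lower boundary is the
bottom of the image and whose upper boundary excludes the ventricular-muscle
band. Vessels of varying usable length are padded (top, with the background
median) or center-cropped to a fixed height, then min-max normalized to [0, 1]
per image — the range the autoencoder's sigmoid output presupposes.

ROI geometry is delineated on one view of a vessel and propagated unchanged to
the other rotational views of the same vessel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import MPRImage

__all__ = [
    "ROI_ROWS",
    "ROI_COLS",
    "ROI_HALF_WIDTH",
    "ROIGeometry",
    "ROIImage",
    "extract_roi",
    "propagate_roi",
    "find_upper_bound",
    "minmax_normalize",
    "extract_cohort_rois",
]

#: Default fixed ROI height (rows); 854 x 41 = 35,014 values per image.
ROI_ROWS = 854
ROI_HALF_WIDTH = 20
ROI_COLS = 2 * ROI_HALF_WIDTH + 1  # 41


@dataclass(frozen=True)
class ROIGeometry:
    """Crop geometry delineated on one view and shared by all views of a vessel."""

    centerline_col: int
    upper_bound_row: int
    target_rows: int = ROI_ROWS


@dataclass
class ROIImage:
    """Fixed-size normalized crop; the unit of feature extraction."""

    pixels: np.ndarray
    source: tuple[str, str, int]
    pad_rows: int = 0
    geometry: ROIGeometry | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != ROI_COLS:
            raise ValueError(f"ROI must have {ROI_COLS} columns, got {self.pixels.shape}")
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12:
            raise ValueError("ROI intensities must lie in [0, 1]")

    @property
    def n_values(self) -> int:
        """Flattened dimension (854 x 41 = 35,014 at the default height)."""
        return int(self.pixels.size)

    def flatten(self) -> np.ndarray:
        """Row-major flattening; the autoencoder input convention."""
        return self.pixels.reshape(-1)


def minmax_normalize(pixels: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a zero-range image maps to all zeros."""
    lo = float(pixels.min())
    hi = float(pixels.max())
    if hi - lo <= 0.0:
        return np.zeros_like(pixels, dtype=float)
    return (pixels - lo) / (hi - lo)


def find_upper_bound(image: MPRImage, search_fraction: float = 0.25) -> int:
    """Heuristic upper ROI boundary: first row below the brightest horizontal band.

    Looks for a bright band (ventricular-muscle-like) in the top
    ``search_fraction`` of the image; returns the first row index under it, or 0
    when no such band stands out. Real-data delineation remains manual; this
    serves synthetic cohorts and smoke tests.
    """
    n_rows = image.pixels.shape[0]
    limit = max(2, int(search_fraction * n_rows))
    row_means = image.pixels[:limit].mean(axis=1)
    overall = image.pixels.mean()
    bright = row_means > max(1.25 * overall, overall + 2 * image.pixels.std() / 4)
    if not bright.any():
        return 0
    last_bright = int(np.nonzero(bright)[0].max())
    return min(last_bright + 1, n_rows - 1)


def extract_roi(
    image: MPRImage,
    upper_bound_row: int | None = None,
    target_rows: int = ROI_ROWS,
    geometry: ROIGeometry | None = None,
) -> ROIImage:
    """Crop, pad/crop to a fixed height, and normalize one view.

    The crop spans columns ``centerline_col +/- 20`` and rows
    ``[upper_bound_row, bottom]``. Shorter crops are padded at the top with the
    background median of the crop; longer crops are center-cropped with any odd
    excess removed from the top. If ``geometry`` is given it overrides both the
    image's own centerline and ``upper_bound_row`` (view propagation).
    """
    pixels = image.pixels
    n_rows, n_cols = pixels.shape
    if geometry is not None:
        centerline = geometry.centerline_col
        upper = geometry.upper_bound_row
        target_rows = geometry.target_rows
    else:
        centerline = image.centerline_col
        upper = (
            upper_bound_row
            if upper_bound_row is not None
            else find_upper_bound(image)
        )
    if upper >= n_rows:
        raise ValueError(f"upper_bound_row {upper} >= image rows {n_rows}")
    lo_col = centerline - ROI_HALF_WIDTH
    hi_col = centerline + ROI_HALF_WIDTH + 1
    if lo_col < 0 or hi_col > n_cols:
        raise ValueError(
            f"centerline too close to the edge for "
            f"{image.patient_id}/{image.vessel_id}/view{image.view_index}: "
            f"columns [{lo_col}, {hi_col}) outside [0, {n_cols})"
        )
    crop = pixels[upper:, lo_col:hi_col]
    usable = crop.shape[0]
    pad_rows = 0
    if usable > target_rows:
        excess = usable - target_rows
        top = excess - excess // 2  # odd excess removed from the top
        crop = crop[top : top + target_rows]
    elif usable < target_rows:
        pad_rows = target_rows - usable
        fill = float(np.median(crop))
        crop = np.vstack([np.full((pad_rows, ROI_COLS), fill), crop])
    return ROIImage(
        pixels=minmax_normalize(crop),
        source=image.key,
        pad_rows=pad_rows,
        geometry=ROIGeometry(centerline, upper, target_rows),
    )


def propagate_roi(reference: ROIGeometry, images: list[MPRImage]) -> list[ROIImage]:
    """Apply one vessel's delineated geometry to all of its views."""
    if not images:
        return []
    vessel = (images[0].patient_id, images[0].vessel_id)
    shape = images[0].pixels.shape
    for img in images:
        if (img.patient_id, img.vessel_id) != vessel:
            raise ValueError("propagate_roi requires views of a single vessel")
        if img.pixels.shape != shape:
            raise ValueError(
                f"shape mismatch across views of {vessel}: "
                f"{img.pixels.shape} vs {shape}"
            )
    return [extract_roi(img, geometry=reference) for img in images]


def extract_cohort_rois(
    images: list[MPRImage], target_rows: int = ROI_ROWS
) -> list[ROIImage]:
    """Delineate on each vessel's first view, propagate to the rest."""
    by_vessel: dict[tuple[str, str], list[MPRImage]] = {}
    for img in images:
        by_vessel.setdefault((img.patient_id, img.vessel_id), []).append(img)
    rois: list[ROIImage] = []
    for views in by_vessel.values():
        views = sorted(views, key=lambda im: im.view_index)
        ref = views[0]
        geometry = ROIGeometry(
            centerline_col=ref.centerline_col,
            upper_bound_row=find_upper_bound(ref),
            target_rows=target_rows,
        )
        rois.extend(propagate_roi(geometry, views))
    return rois
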