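"""Cell segmentation from a reference channel and rolling-ball background
subtraction.

Single cells are segmented from a bright-field-like reference channel by
automatic (Otsu) thresholding, hole filling, minimum-area filtering and
removal of border-touching objects.  Background is removed with the classic
rolling-ball estimate — a grayscale opening with a ball structuring element
of the given radius (default 50 px) — and the result is clipped at zero.

Pixel coordinates are 0-based; bounding boxes are half-open
``(min_row, min_col, max_row, max_col)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage import filters, measure, restoration, segmentation

__all__ = ["CellMask", "subtract_background", "segment_cells", "write_masks"]


@dataclass
class CellMask:
    """One segmented cell: full-frame boolean mask plus summary geometry."""

    label_id: int
    mask: np.ndarray
    centroid_xy: tuple[float, float]  # (x, y), px
    area_px: int
    area_um2: float
    bbox: tuple[int, int, int, int]  # half-open (min_row, min_col, max_row, max_col)

    def __post_init__(self) -> None:
        if self.area_px <= 0:
            raise ValueError("mask must be nonempty")
        x, y = self.centroid_xy
        r0, c0, r1, c1 = self.bbox
        if not (c0 <= x < c1 and r0 <= y < r1):
            raise ValueError("centroid must lie inside the bounding box")


def subtract_background(image: np.ndarray, ball_radius_px: int = 50) -> np.ndarray:
    """Subtract a rolling-ball background estimate and clip at zero.

    The background is the surface traced by a ball of radius
    ``ball_radius_px`` rolled under the intensity landscape; subtracting it
    removes smooth, large-scale illumination while leaving features sharper
    than the ball untouched.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if ball_radius_px < 1:
        raise ValueError("ball radius must be >= 1")
    if ball_radius_px >= min(image.shape):
        raise ValueError("ball radius exceeds image extent")
    background = restoration.rolling_ball(image, radius=ball_radius_px)
    return np.clip(image - background, 0.0, None)


def segment_cells(
    reference_channel: np.ndarray,
    min_area_um2: float,
    pixel_size_um: float,
    exclude_border: bool = True,
    threshold: float | None = None,
) -> list[CellMask]:
    """Segment individual cells from the reference channel.

    Pipeline: automatic Otsu threshold (or a caller-supplied absolute
    ``threshold``) -> fill holes -> drop objects below ``min_area_um2`` ->
    drop objects touching the image border (optional) -> connected-component
    labels.  Returns cells sorted by descending area.  A constant image
    yields an empty list rather than an error.
    """
    image = np.asarray(reference_channel, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("reference channel must be 2D")
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    if min_area_um2 <= 0:
        raise ValueError("min_area_um2 must be positive")

    if image.max() == image.min():
        return []
    thr = filters.threshold_otsu(image) if threshold is None else threshold
    binary = image > thr
    binary = ndi.binary_fill_holes(binary)
    min_area_px = int(np.ceil(min_area_um2 / pixel_size_um**2))
    lab, n = ndi.label(binary, structure=np.ones((3, 3), bool))
    if n:
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        binary = (sizes >= min_area_px)[lab]
    if exclude_border:
        binary = segmentation.clear_border(binary)
    labels = measure.label(binary, connectivity=2)

    cells: list[CellMask] = []
    for rp in measure.regionprops(labels):
        cells.append(
            CellMask(
                label_id=rp.label,
                mask=labels == rp.label,
                centroid_xy=(rp.centroid[1], rp.centroid[0]),
                area_px=int(rp.area),
                area_um2=float(rp.area) * pixel_size_um**2,
                bbox=tuple(rp.bbox),  # type: ignore[arg-type]
            )
        )
    cells.sort(key=lambda c: c.area_px, reverse=True)
    for i, c in enumerate(cells, start=1):
        c.label_id = i
    return cells


def write_masks(
    path_tiff: str | Path,
    path_csv: str | Path,
    cells: list[CellMask],
    shape: tuple[int, int],
) -> None:
    """Write a 16-bit label image and a per-cell CSV (label, centroid, area)."""
    labels = np.zeros(shape, dtype=np.uint16)
    for c in cells:
        labels[c.mask] = c.label_id
    tifffile.imwrite(str(path_tiff), labels)
    pd.DataFrame(
        [
            {
                "label": c.label_id,
                "centroid_x_px": c.centroid_xy[0],
                "centroid_y_px": c.centroid_xy[1],
                "area_px": c.area_px,
                "area_um2": c.area_um2,
            }
            for c in cells
        ]
    ).to_csv(path_csv, index=False)
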