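"""Segmentation of single-plant carrot photographs.

A plant is photographed on a white baseboard divided by a black horizontal
line: the shoot is arranged above the line, the storage root below it, and
the crown (shoot/root junction) sits in a central gap in the line.  This
module turns such an RGB photograph into a clean binary plant mask, locates
the divider line, and splits the mask into shoot and root sections with a
crown point anchoring downstream profile analyses.

Conventions: rows increase downward, origin top-left, 0-based indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray, rgb2hsv
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

__all__ = [
    "PlantMask",
    "PlantSegments",
    "SegmentationError",
    "binarize_plant",
    "detect_divider",
    "split_and_locate_crown",
    "segment_image",
    "qc_overlay",
]


class SegmentationError(ValueError):
    """Raised when an image cannot be segmented into a usable plant mask."""


@dataclass(frozen=True)
class PlantMask:
    """Binary foreground mask of a plant (or plant section).

    grid is a HxW uint8 array with values in {0, 1}; foreground_count is
    the number of foreground (1) pixels.
    """

    grid: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        vals = np.unique(grid)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask grid must be binary {0,1}")
        object.__setattr__(self, "grid", grid.astype(np.uint8))

    @property
    def foreground_count(self) -> int:
        return int(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass(frozen=True)
class PlantSegments:
    """Shoot/root split of a plant mask around the baseboard divider.

    Every shoot foreground pixel lies strictly above the divider band and
    every root pixel strictly below it; the crown sits on the divider row at
    the horizontal midpoint of the top of the storage root.
    """

    shoot_mask: PlantMask
    root_mask: PlantMask
    divider_row: int
    crown: tuple[int, int]  # (row, col)


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    if image.shape[0] < 2 or image.shape[1] < 2:
        raise ValueError("image too small")
    return image


def binarize_plant(
    image: np.ndarray,
    min_object_fraction: float = 1e-4,
) -> PlantMask:
    """Binarize a plant photograph into foreground (plant) and background.

    The image is converted to grayscale and to HSV; the saturation channel
    (rescaled to the gray range) is subtracted from the grayscale image and
    the difference clamped at zero.  Otsu's method thresholds the difference,
    with polarity chosen so the plant — darker than the white baseboard —
    is foreground.  Connected components (8-connectivity) smaller than
    ``min_object_fraction`` of the image area are removed.

    Raises
    ------
    SegmentationError
        If the image has no contrast, or cleanup leaves an empty mask.
    """
    image = _validate_rgb(image)
    gray = rgb2gray(image)          # in [0, 1]
    sat = rgb2hsv(image)[..., 1]    # in [0, 1], same range as gray
    diff = np.clip(gray - sat, 0.0, 1.0)
    if np.ptp(diff) == 0:
        raise SegmentationError("no contrast")
    thresh = threshold_otsu(diff)
    fg = diff < thresh  # plant is dark-on-white in the difference image
    # polarity guard: the plant should be the minority class
    if fg.mean() > 0.5:
        fg = ~fg
    min_size = int(np.ceil(min_object_fraction * fg.size))
    if min_size > 1:
        # remove components strictly smaller than min_size (8-connectivity)
        fg = remove_small_objects(fg, max_size=min_size - 1, connectivity=2)
    if not fg.any():
        raise SegmentationError("no plant detected")
    return PlantMask(fg.astype(np.uint8))


def detect_divider(
    image: np.ndarray,
    darkness_margin: float = 0.2,
) -> int:
    """Locate the black horizontal divider line on the baseboard.

    For each row, the median grayscale intensity is computed; the divider
    is the darkest such row.  The median (rather than mean) bridges the
    central gap where the carrot crown sits, since the line spans most of
    the image width.  The line is several pixels thick, so contiguous rows
    at the minimum darkness are collapsed to their central row; between
    separated equally dark candidates the topmost is returned.

    Raises
    ------
    SegmentationError
        If no row is darker than the image-wide median intensity by at
        least ``darkness_margin`` (on the 0–1 gray scale).
    """
    image = _validate_rgb(image)
    gray = rgb2gray(image)
    row_medians = np.median(gray, axis=1)
    darkest = float(row_medians.min())
    background = float(np.median(gray))
    if background - darkest < darkness_margin:
        raise SegmentationError("divider not found")
    # contiguous run of rows at the minimum (the line's thickness)
    at_min = np.flatnonzero(row_medians <= darkest + 1e-9)
    top = int(at_min[0])  # topmost candidate run wins on ties
    run_end = top
    while run_end + 1 < len(row_medians) and \
            row_medians[run_end + 1] <= darkest + 1e-9:
        run_end += 1
    return (top + run_end) // 2


def split_and_locate_crown(
    mask: PlantMask,
    divider_row: int,
    band_half_height: int = 3,
    border_policy: str = "error",
) -> PlantSegments:
    """Split a plant mask at the divider and locate the crown point.

    Rows within ``band_half_height`` of ``divider_row`` (the divider line
    itself plus a safety margin) are excluded from both sections.  The crown
    is placed on the divider row at the midpoint of the foreground span in
    the first root row below the band: storage-root tissue is contiguous at
    the junction, whereas petioles may straddle the gap.

    ``border_policy`` controls what happens when plant foreground touches
    the image border ("error" or "warn") — such photographs were staging
    failures in the original acquisition protocol.
    """
    grid = mask.grid
    h, w = grid.shape
    if not 0 <= divider_row < h:
        raise ValueError("divider_row outside image")
    if border_policy not in ("error", "warn", "ignore"):
        raise ValueError("border_policy must be error|warn|ignore")

    lo = divider_row - band_half_height
    hi = divider_row + band_half_height

    shoot = grid.copy()
    shoot[max(lo, 0):, :] = 0
    root = grid.copy()
    root[: min(hi + 1, h), :] = 0

    # border check on the plant sections only: the divider line itself
    # legitimately spans the full image width
    plant = shoot | root
    border_touch = (
        plant[0, :].any() or plant[-1, :].any()
        or plant[:, 0].any() or plant[:, -1].any()
    )
    if border_touch:
        if border_policy == "error":
            raise SegmentationError("plant overlaps image border")
        if border_policy == "warn":
            warnings.warn("plant overlaps image border", stacklevel=2)

    if not shoot.any():
        raise SegmentationError("no shoot foreground above divider")
    if not root.any():
        raise SegmentationError("no root foreground below divider")

    first_root_row = int(np.argmax(root.any(axis=1)))
    cols = np.flatnonzero(root[first_root_row])
    crown_col = int(round((cols[0] + cols[-1]) / 2.0))
    return PlantSegments(
        shoot_mask=PlantMask(shoot),
        root_mask=PlantMask(root),
        divider_row=int(divider_row),
        crown=(int(divider_row), crown_col),
    )


def segment_image(
    image: np.ndarray,
    min_object_fraction: float = 1e-4,
    band_half_height: int = 3,
    border_policy: str = "error",
    darkness_margin: float = 0.2,
) -> PlantSegments:
    """Full segmentation: binarize, find the divider, split, locate crown."""
    mask = binarize_plant(image, min_object_fraction=min_object_fraction)
    divider = detect_divider(image, darkness_margin=darkness_margin)
    return split_and_locate_crown(
        mask, divider,
        band_half_height=band_half_height,
        border_policy=border_policy,
    )


def qc_overlay(image: np.ndarray, segments: PlantSegments) -> np.ndarray:
    """Render a QC image: shoot in green, root in orange, divider and crown.

    Returns an HxWx3 uint8 array suitable for writing as PNG next to the
    per-image measurement record, so each segmentation can be eyeballed.
    """
    image = _validate_rgb(image)
    out = image.astype(np.uint8).copy()
    out[segments.shoot_mask.grid.astype(bool)] = (0, 180, 0)
    out[segments.root_mask.grid.astype(bool)] = (230, 120, 0)
    out[segments.divider_row, :] = (255, 0, 0)
    r, c = segments.crown
    h, w = out.shape[:2]
    out[max(r - 6, 0):min(r + 7, h), max(c - 1, 0):min(c + 2, w)] = (0, 0, 255)
    out[max(r - 1, 0):min(r + 2, h), max(c - 6, 0):min(c + 7, w)] = (0, 0, 255)
    return out
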