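"""Procedural generation of carrot-like single-plant photographs.

Renders the staged-photograph geometry the pipeline expects — white
baseboard, black horizontal divider with a central gap, shoot (petiole fan
plus leaf blobs) above the line and storage root below it — with complete
ground-truth metadata (exact per-section pixel counts, petiole count/width/
length, root taper), so every pipeline stage can be tested without any
external image set.

The storage-root silhouette family is a power-law taper blended with an
elliptical tip cap: half-width

    w(z) = (W/2) * (1 - z/L)^k * cap(z/L),

where cap is 1 outside the tip region and an elliptical roll-off over the
last ``tip_bluntness`` fraction of the root.  Two scalar knobs (k and
tip_bluntness) span the conical-vs-cylindrical and tapered-vs-blunt-tip
axes of root shape variation.

The default population couples petiole count, mean petiole length and
petiole width through a shared per-plant vigor factor with independent
per-trait noise: shoot architectural traits covary with overall plant size
(allometric scaling), and an uncorrelated draw would be the unrealistic
choice for a crop population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad

__all__ = [
    "SyntheticPlantSpec",
    "render_plant",
    "generate_population",
    "root_half_width",
    "DEFAULT_HEIGHT",
    "DEFAULT_WIDTH",
    "DEFAULT_DIVIDER_ROW",
    "DEFAULT_PX_PER_CM",
]

DEFAULT_HEIGHT = 720
DEFAULT_WIDTH = 600
DEFAULT_DIVIDER_ROW = 470
DEFAULT_PX_PER_CM = 10.0
DIVIDER_HALF_THICKNESS = 2

BG_COLOR = (255, 255, 255)
SHOOT_COLOR = (60, 140, 50)
ROOT_COLOR = (225, 120, 35)
LINE_COLOR = (0, 0, 0)

# label-canvas codes used for exact ground-truth pixel counts
_LAB_SHOOT, _LAB_ROOT, _LAB_LINE = 1, 2, 3


@dataclass(frozen=True)
class SyntheticPlantSpec:
    """Full parametric description of one synthetic plant image.

    petioles is a list of (angle_deg, length_px, width_px, blob_radius_px)
    with angles measured from the +x axis (so 90 is straight up); all
    petioles must point into the upper half-plane.
    """

    seed: int
    height: int = DEFAULT_HEIGHT
    width: int = DEFAULT_WIDTH
    divider_row: int = DEFAULT_DIVIDER_ROW
    crown_col: int = DEFAULT_WIDTH // 2
    root_length_px: float = 180.0
    root_max_width_px: float = 50.0
    taper_k: float = 1.0
    tip_bluntness: float = 0.2
    petioles: tuple = field(default_factory=tuple)

    def __post_init__(self):
        for ang, length, w, _ in self.petioles:
            if not (0.0 < ang < 180.0):
                raise ValueError("petiole angles must lie in the upper half-plane")
            if w < 2:
                raise ValueError("petiole widths must be >= 2 px")
        if self.root_max_width_px < 2:
            raise ValueError("root width must be >= 2 px")
        if not 0.0 <= self.tip_bluntness <= 1.0:
            raise ValueError("tip_bluntness must be in [0, 1]")
        if self.taper_k < 0:
            raise ValueError("taper exponent must be >= 0")


def root_half_width(spec: SyntheticPlantSpec, z: float) -> float:
    """Continuous half-width of the storage root at depth z px below the crown."""
    L = spec.root_length_px
    if z < 0 or z >= L:
        return 0.0
    t = z / L
    half = (spec.root_max_width_px / 2.0) * (1.0 - t) ** spec.taper_k
    b = spec.tip_bluntness
    if b > 0 and t > 1.0 - b:
        u = (t - (1.0 - b)) / b
        half *= float(np.sqrt(max(0.0, 1.0 - u**2)))
    return half


def _validate_extents(spec: SyntheticPlantSpec, margin: int = 2) -> None:
    H, W = spec.height, spec.width
    if spec.divider_row + DIVIDER_HALF_THICKNESS + spec.root_length_px >= H - margin:
        raise ValueError("spec exceeds canvas: root runs off the bottom")
    if spec.crown_col - spec.root_max_width_px / 2 < margin or \
            spec.crown_col + spec.root_max_width_px / 2 >= W - margin:
        raise ValueError("spec exceeds canvas: root wider than canvas")
    for ang, length, w, blob_r in spec.petioles:
        tip_r = spec.divider_row - length * np.sin(np.deg2rad(ang))
        tip_c = spec.crown_col + length * np.cos(np.deg2rad(ang))
        reach = blob_r + w / 2 + margin
        if tip_r - reach < 0:
            raise ValueError("spec exceeds canvas: petiole runs off the top")
        if tip_c - reach < 0 or tip_c + reach >= W:
            raise ValueError("spec exceeds canvas: petiole runs off the side")


def _draw_capsule(labels, p0, p1, half_width, code, row_max):
    """Rasterize a thick line segment (capsule) onto the label canvas,
    clipped to rows <= row_max so petioles never spill below the crown."""
    H, W = labels.shape
    r0 = max(int(min(p0[0], p1[0]) - half_width - 1), 0)
    r1 = min(int(max(p0[0], p1[0]) + half_width + 2), min(H, row_max + 1))
    c0 = max(int(min(p0[1], p1[1]) - half_width - 1), 0)
    c1 = min(int(max(p0[1], p1[1]) + half_width + 2), W)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr, dc = p1[0] - p0[0], p1[1] - p0[1]
    seg2 = dr * dr + dc * dc
    if seg2 == 0:
        dist = np.hypot(rr - p0[0], cc - p0[1])
    else:
        t = np.clip(((rr - p0[0]) * dr + (cc - p0[1]) * dc) / seg2, 0.0, 1.0)
        dist = np.hypot(rr - (p0[0] + t * dr), cc - (p0[1] + t * dc))
    labels[r0:r1, c0:c1][dist < half_width] = code


def _draw_disk(labels, center, radius, code):
    H, W = labels.shape
    r0 = max(int(center[0] - radius - 1), 0)
    r1 = min(int(center[0] + radius + 2), H)
    c0 = max(int(center[1] - radius - 1), 0)
    c1 = min(int(center[1] + radius + 2), W)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 < radius**2
    labels[r0:r1, c0:c1][inside] = code


def render_plant(
    spec: SyntheticPlantSpec,
    band_half_height: int = 3,
    px_per_cm: float = DEFAULT_PX_PER_CM,
) -> tuple[np.ndarray, dict]:
    """Render a spec to an RGB image plus a ground-truth record.

    The record includes exact foreground pixel counts (total, and per
    section outside the divider band of the given half-height), the
    analytic root area 2*integral(w(z)dz), and every generative parameter.
    Rendering is deterministic: the same spec yields a bit-identical image.
    """
    _validate_extents(spec)
    H, W = spec.height, spec.width
    labels = np.zeros((H, W), dtype=np.uint8)

    # divider line with a central gap around the crown
    gap_half = max(spec.root_max_width_px / 2 + 12, 30)
    r0 = spec.divider_row - DIVIDER_HALF_THICKNESS
    r1 = spec.divider_row + DIVIDER_HALF_THICKNESS + 1
    labels[r0:r1, :] = _LAB_LINE
    g0 = max(int(spec.crown_col - gap_half), 0)
    g1 = min(int(spec.crown_col + gap_half) + 1, W)
    labels[r0:r1, g0:g1] = 0

    # storage root: row-wise fill below the crown
    L = spec.root_length_px
    n_rows = int(np.floor(L))
    for z in range(n_rows):
        half = root_half_width(spec, z + 0.5)
        if half <= 0:
            continue
        row = spec.divider_row + 1 + z
        c0 = int(np.ceil(spec.crown_col - half))
        c1 = int(np.floor(spec.crown_col + half))
        labels[row, c0:c1 + 1] = _LAB_ROOT

    # petiole fan + leaf blobs, clipped to the shoot half-plane
    crown = (float(spec.divider_row), float(spec.crown_col))
    for ang, length, w, blob_r in spec.petioles:
        rad = np.deg2rad(ang)
        tip = (crown[0] - length * np.sin(rad), crown[1] + length * np.cos(rad))
        _draw_capsule(labels, crown, tip, w / 2.0, _LAB_SHOOT,
                      row_max=spec.divider_row)
        _draw_disk(labels, tip, blob_r, _LAB_SHOOT)

    image = np.empty((H, W, 3), dtype=np.uint8)
    image[:] = BG_COLOR
    image[labels == _LAB_LINE] = LINE_COLOR
    image[labels == _LAB_ROOT] = ROOT_COLOR
    image[labels == _LAB_SHOOT] = SHOOT_COLOR

    rows = np.arange(H)[:, None]
    shoot_px = int(((labels == _LAB_SHOOT) &
                    (rows < spec.divider_row - band_half_height)).sum())
    root_px = int(((labels == _LAB_ROOT) &
                   (rows > spec.divider_row + band_half_height)).sum())
    root_area_analytic = 2.0 * quad(
        lambda z: root_half_width(spec, z), 0.0, L, limit=200)[0]

    lengths = [p[1] for p in spec.petioles]
    widths = [p[2] for p in spec.petioles]
    truth = {
        "seed": spec.seed,
        "height": H,
        "width": W,
        "divider_row": spec.divider_row,
        "crown_col": spec.crown_col,
        "band_half_height": band_half_height,
        "px_per_cm": px_per_cm,
        "petiole_count": len(spec.petioles),
        "petiole_width_px": float(np.mean(widths)) if widths else 0.0,
        "petiole_length_px": float(np.mean(lengths)) if lengths else 0.0,
        "petiole_width_cm": (float(np.mean(widths)) / px_per_cm) if widths else 0.0,
        "petiole_length_cm": (float(np.mean(lengths)) / px_per_cm) if lengths else 0.0,
        "root_length_px": float(L),
        "root_max_width_px": float(spec.root_max_width_px),
        "taper_k": float(spec.taper_k),
        "tip_bluntness": float(spec.tip_bluntness),
        "root_area_analytic_px": float(root_area_analytic),
        "root_area_px": int((labels == _LAB_ROOT).sum()),
        "shoot_area_px": int((labels == _LAB_SHOOT).sum()),
        "shoot_pixels": shoot_px,
        "root_pixels": root_px,
        "total_foreground": int((labels > 0).sum()),
    }
    return image, truth


_DEFAULT_RANGES = {
    "petiole_count": (5, 15),
    "petiole_length": (80.0, 380.0),
    "petiole_width": (4.0, 14.0),
    "root_length": (120.0, 230.0),
    "root_max_width": (30.0, 80.0),
    "taper_k": (0.3, 2.0),
    "tip_bluntness": (0.05, 0.6),
}

# mixing weight of the shared vigor factor for each coupled shoot trait
_VIGOR_WEIGHT = {"petiole_count": 0.75, "petiole_length": 0.75,
                 "petiole_width": 0.6}


def _draw_param(rng, name, ranges, overrides, s):
    """Draw one plant parameter: overridden params are independent uniform
    (or fixed); coupled shoot traits mix the vigor factor s with noise."""
    if overrides and name in overrides:
        ov = overrides[name]
        if np.isscalar(ov):
            return float(ov)
        lo, hi = ov
        if lo > hi:
            raise ValueError(f"empty range for {name}: ({lo}, {hi})")
        return rng.uniform(lo, hi)
    lo, hi = ranges[name]
    if name in _VIGOR_WEIGHT:
        w = _VIGOR_WEIGHT[name]
        frac = w * s + (1 - w) * rng.uniform()
    else:
        frac = rng.uniform()
    return lo + (hi - lo) * frac


def generate_population(
    n: int,
    seed: int,
    overrides: dict | None = None,
    height: int = DEFAULT_HEIGHT,
    width: int = DEFAULT_WIDTH,
    divider_row: int = DEFAULT_DIVIDER_ROW,
    px_per_cm: float = DEFAULT_PX_PER_CM,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Generate a reproducible population of synthetic plants.

    Returns (images, truth_table); the table has one row per image with an
    image_id column plus the full ground-truth record.  ``overrides`` maps
    parameter names (petiole_count, petiole_length, petiole_width,
    root_length, root_max_width, taper_k, tip_bluntness, crown_jitter) to a
    constant or a (lo, hi) uniform range drawn independently of the vigor
    factor — used to build controlled populations varying a single knob.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if overrides:
        for name, ov in overrides.items():
            if name != "crown_jitter" and name not in _DEFAULT_RANGES:
                raise ValueError(f"unknown parameter {name!r}")
            if not np.isscalar(ov) and ov[0] > ov[1]:
                raise ValueError(f"empty range for {name}")
    rng = np.random.default_rng(seed)
    images, rows = [], []
    for i in range(n):
        s = rng.uniform()  # per-plant vigor factor
        count = int(np.clip(round(_draw_param(
            rng, "petiole_count", _DEFAULT_RANGES, overrides, s)), 1, None))
        mean_len = _draw_param(rng, "petiole_length", _DEFAULT_RANGES, overrides, s)
        pet_w = _draw_param(rng, "petiole_width", _DEFAULT_RANGES, overrides, s)
        jitter = 15.0
        if overrides and "crown_jitter" in overrides:
            jitter = float(overrides["crown_jitter"])
        crown_col = int(width // 2 + rng.uniform(-jitter, jitter))

        angles = np.linspace(60.0, 120.0, count) + rng.uniform(-4, 4, count)
        lengths = mean_len * (1.0 + rng.uniform(-0.08, 0.08, count))
        blob_r = 6.0 + 0.04 * lengths + rng.uniform(0, 4, count)
        petioles = tuple(
            (float(a), float(l), float(pet_w), float(b))
            for a, l, b in zip(angles, lengths, blob_r)
        )
        spec = SyntheticPlantSpec(
            seed=seed + i,
            height=height, width=width, divider_row=divider_row,
            crown_col=crown_col,
            root_length_px=_draw_param(rng, "root_length", _DEFAULT_RANGES, overrides, s),
            root_max_width_px=_draw_param(rng, "root_max_width", _DEFAULT_RANGES, overrides, s),
            taper_k=_draw_param(rng, "taper_k", _DEFAULT_RANGES, overrides, s),
            tip_bluntness=_draw_param(rng, "tip_bluntness", _DEFAULT_RANGES, overrides, s),
            petioles=petioles,
        )
        image, truth = render_plant(spec, px_per_cm=px_per_cm)
        truth["image_id"] = f"plant_{i:04d}"
        images.append(image)
        rows.append(truth)
    return images, pd.DataFrame(rows)
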