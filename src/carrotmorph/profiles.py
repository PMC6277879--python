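"""Digital biomass profiles of carrot shoots and storage roots.

The shoot biomass profile (SBP) integrates the binary shoot mask along the
angular sweeps of a half-elliptical grid anchored at the crown: bin i of an
n-bin profile counts the foreground pixels whose normalized elliptical
radius falls in [i/n, (i+1)/n).  The root biomass profile is the foreground
pixel count per image row over the storage-root extent, resampled to a
fixed length; dividing by its maximum then gives the length-and-width
normalized shape profile used for population PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .imaging import PlantMask

__all__ = [
    "BiomassProfile",
    "shoot_biomass_profile",
    "root_biomass_profile",
    "normalize_root_profile",
]

DEFAULT_N_BINS = 1000


@dataclass(frozen=True)
class BiomassProfile:
    """Fixed-length digital biomass vector.

    kind is "shoot-radial" (pixel count per normalized elliptical radius
    bin) or "root-depth" (pixel count per normalized depth).  For an
    unnormalized shoot profile the values sum exactly to source_area_px.
    """

    values: np.ndarray
    kind: str
    source_area_px: int
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("profile values must be 1-D")
        if (values < 0).any():
            raise ValueError("profile values must be nonnegative")
        if self.kind not in ("shoot-radial", "root-depth"):
            raise ValueError("kind must be 'shoot-radial' or 'root-depth'")
        object.__setattr__(self, "values", values)

    @property
    def n_bins(self) -> int:
        return self.values.size


def _elliptical_semi_axes(
    shoot: np.ndarray, crown: tuple[int, int]
) -> tuple[float, float]:
    """Semi-axes of the half-elliptical grid: the crown-centered half
    bounding box of the shoot, so every shoot pixel has radius <= 1."""
    rows, cols = np.nonzero(shoot)
    cy, cx = crown
    a = float(np.abs(cols - cx).max())
    b = float(np.abs(cy - rows).max())
    return max(a, 1.0), max(b, 1.0)


def shoot_biomass_profile(
    shoot: PlantMask,
    crown: tuple[int, int],
    n: int = DEFAULT_N_BINS,
    semi_axes: tuple[float, float] | None = None,
) -> BiomassProfile:
    """Shoot biomass profile on a crown-anchored half-elliptical grid.

    Each foreground pixel (row y, col x) gets normalized radius
    rho = sqrt(((x-cx)/a)^2 + ((y-cy)/b)^2); bin i counts pixels with
    rho in [i/n, (i+1)/n), pixels at rho == 1 falling in the last bin.
    The semi-axes default to the crown-centered half bounding box of the
    shoot, so rho <= 1 for every pixel and the profile total equals the
    shoot pixel count exactly (conservation).

    An empty mask yields an all-zero profile (not an error): an empty
    shoot is a measurable degenerate outcome, unlike a missing root.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = shoot.grid
    cy, cx = crown
    values = np.zeros(n, dtype=float)
    if not grid.any():
        return BiomassProfile(values, "shoot-radial", 0,
                              meta={"crown": (cy, cx)})
    rows, cols = np.nonzero(grid)
    if (rows > cy).any():
        warnings.warn("crown lies above some shoot pixels", stacklevel=2)
    if semi_axes is None:
        a, b = _elliptical_semi_axes(grid, (cy, cx))
    else:
        a, b = semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")
    rho = np.sqrt(((cols - cx) / a) ** 2 + ((rows - cy) / b) ** 2)
    idx = np.minimum((rho * n).astype(int), n - 1)  # rho == 1 -> last bin
    np.add.at(values, idx, 1.0)
    return BiomassProfile(
        values, "shoot-radial", int(grid.sum()),
        meta={"crown": (int(cy), int(cx)), "semi_axes": (a, b)},
    )


def root_biomass_profile(root: PlantMask, n: int = DEFAULT_N_BINS) -> BiomassProfile:
    """Root biomass profile: foreground count per row, resampled to n points.

    Row sums are taken from the first to the last nonzero row of the root
    mask (so stray rows cleaned elsewhere cannot stretch the profile) and
    linearly interpolated onto n evenly spaced depths over that extent.
    source_area_px is the raw (pre-resampling) pixel total.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = root.grid
    if not grid.any():
        raise ValueError("no root")
    row_sums = grid.sum(axis=1).astype(float)
    nz = np.flatnonzero(row_sums)
    raw = row_sums[nz[0]: nz[-1] + 1]
    if raw.size == 1:
        values = np.full(n, raw[0])
    else:
        x_old = np.linspace(0.0, 1.0, raw.size)
        x_new = np.linspace(0.0, 1.0, n)
        values = np.interp(x_new, x_old, raw)
    return BiomassProfile(
        values, "root-depth", int(raw.sum()),
        meta={"extent_rows": (int(nz[0]), int(nz[-1]))},
    )


def normalize_root_profile(
    profile: BiomassProfile, width_by: str = "max"
) -> BiomassProfile:
    """Normalize a root profile by length and width for shape analysis.

    Length normalization is the fixed-n resampling already applied by
    :func:`root_biomass_profile`; width normalization divides by the
    profile maximum (``width_by="max"``, default) so the output lies in
    [0, 1] with max exactly 1.  ``width_by="first"`` divides by the crown-
    end row sum instead, exposed because the original width convention is
    not uniquely determined.
    """
    if profile.kind != "root-depth":
        raise ValueError("can only normalize root-depth profiles")
    if profile.values.max() <= 0:
        raise ValueError("all-zero profile cannot be normalized")
    if width_by == "max":
        denom = profile.values.max()
    elif width_by == "first":
        denom = profile.values[0]
        if denom <= 0:
            raise ValueError("crown-end value is zero")
    else:
        raise ValueError("width_by must be 'max' or 'first'")
    return BiomassProfile(
        profile.values / denom, "root-depth", profile.source_area_px,
        normalized=True, meta=dict(profile.meta),
    )
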