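"""Threat-based habitat degradation and quality.

Degradation of a habitat cell x (class j) sums distance-decayed exposure to
every threat-emitting cell y over all threat factors r:

    D_x = sum_r sum_y (W_r / sum W) * max(0, 1 - d_xy / d_rmax) * beta * S_jr

with d_xy the Euclidean centre-to-centre distance and linear decay (the only
decay implemented). The sum runs over all threat cells within d_rmax with no
per-threat averaging. Quality then saturates with degradation,

    Q_x = H_j * (1 - D_x^z / (D_x^z + k^z))

where H_j is the class's habitat suitability, z a shape exponent (default
2.5) and k the half-saturation constant, by default half the maximum
observed degradation.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grid_io import Grid, LandUseGrid, LookupTable

__all__ = [
    "ThreatSpec",
    "QualityParams",
    "degradation",
    "quality",
    "half_saturation_default",
]


@dataclasses.dataclass(frozen=True)
class ThreatSpec:
    """One threat factor: which classes emit it, how strong, how far."""

    name: str
    source_classes: tuple[int, ...]
    weight: float
    max_distance: float  # metres
    decay: str = "linear"

    def __post_init__(self) -> None:
        if not self.source_classes:
            raise ValueError("a threat needs at least one source class")
        if self.weight < 0:
            raise ValueError("threat weight must be >= 0")
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if self.decay != "linear":
            raise NotImplementedError("only linear decay is implemented")


@dataclasses.dataclass
class QualityParams:
    z: float = 2.5
    half_saturation: float | None = None  # None -> half-max rule
    beta: float = 1.0  # accessibility / legal protection, constant by default

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("z must be positive")
        if self.half_saturation is not None and self.half_saturation <= 0:
            raise ValueError("half_saturation must be positive")
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must lie in [0, 1]")


def _decay_kernel(max_distance: float, cell_size: float) -> np.ndarray:
    """Linear-decay stencil: 1 - d/d_rmax for d <= d_rmax, else 0."""
    radius = int(np.floor(max_distance / cell_size))
    offs = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    d = np.hypot(dy, dx) * cell_size
    return np.where(d <= max_distance, 1.0 - d / max_distance, 0.0)


def _sensitivity_map(landuse: LandUseGrid, habitat_table: LookupTable, column: str) -> np.ndarray:
    lut = habitat_table.column(column)
    out = np.zeros(landuse.shape)
    for code, s in lut.items():
        if not 0 <= s <= 1:
            raise ValueError(f"{column} for class {code} outside [0, 1]")
        out[landuse.values == code] = s
    return out


def degradation(
    landuse: LandUseGrid,
    threats: Sequence[ThreatSpec],
    habitat_table: LookupTable,
    beta: float | Grid = 1.0,
) -> Grid:
    """Per-cell habitat degradation D.

    ``habitat_table`` must hold one sensitivity column ``S_<threat name>``
    per threat (values in [0, 1]). The exposure sum per threat is evaluated
    as a spatial correlation with the linear-decay stencil, which is exactly
    the pairwise double loop.
    """
    if not threats:
        raise ValueError("at least one threat is required")
    sum_w = sum(t.weight for t in threats)
    if sum_w <= 0:
        raise ValueError("threat weights sum to zero")
    codes = set(int(c) for c in np.unique(landuse.values[landuse.mask]))
    habitat_table.require(codes, ["H"] + [f"S_{t.name}" for t in threats])

    beta_arr = beta.values if isinstance(beta, Grid) else np.full(landuse.shape, float(beta))
    D = np.zeros(landuse.shape)
    for t in threats:
        src = np.isin(landuse.values, t.source_classes) & landuse.mask
        kernel = _decay_kernel(t.max_distance, landuse.cell_size)
        exposure = ndimage.correlate(src.astype(float), kernel, mode="constant", cval=0.0)
        sens = _sensitivity_map(landuse, habitat_table, f"S_{t.name}")
        D += (t.weight / sum_w) * exposure * sens * beta_arr
    out = np.where(landuse.mask, D, -9999.0)
    return Grid(out, cell_size=landuse.cell_size, origin=landuse.origin, nodata=-9999.0)


def half_saturation_default(D: Grid) -> float:
    """The half-max rule: k = max(D)/2, falling back to 0.5 for all-zero D."""
    dmax = float(D.valid_values().max())
    if dmax <= 0:
        warnings.warn("degradation is zero everywhere; using k = 0.5")
        return 0.5
    return dmax / 2.0


def quality(
    landuse: LandUseGrid,
    D: Grid,
    habitat_table: LookupTable,
    params: QualityParams | None = None,
) -> Grid:
    """Habitat quality Q = H_j * (1 - D^z / (D^z + k^z)), in [0, H_j]."""
    from .grid_io import assert_aligned

    assert_aligned(landuse, D)
    params = params or QualityParams()
    k = params.half_saturation if params.half_saturation is not None else half_saturation_default(D)
    H = _sensitivity_map(landuse, habitat_table, "H")
    valid = landuse.mask & D.mask
    out = np.full(landuse.shape, -9999.0)
    d = D.values[valid]
    out[valid] = H[valid] * (1.0 - d**params.z / (d**params.z + k**params.z))
    return Grid(out, cell_size=landuse.cell_size, origin=landuse.origin, nodata=-9999.0)
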