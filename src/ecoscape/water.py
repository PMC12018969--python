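"""Annual water yield from the Budyko-curve water balance.

Per-cell yield is precipitation minus actual evapotranspiration, with the
evaporative fraction given by the Fuh/Zhang form of the Budyko curve:

    AET/P = 1 + PET/P - (1 + (PET/P)^omega)^(1/omega)
    omega = Z * AWC / P + 1.25

where P is annual precipitation (mm), PET potential evapotranspiration
(mm), AWC plant-available water content (mm) and Z a dimensionless
seasonality constant (default 10, valid range (0, 30]). All water reaching
a cell is assumed to leave it as runoff, so no routing is performed.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .grid_io import Grid, assert_aligned

__all__ = ["WaterYieldInputs", "omega_grid", "aet_ratio", "water_yield", "total_yield_volume"]

DEFAULT_Z = 10.0


@dataclasses.dataclass
class WaterYieldInputs:
    P: Grid  # annual precipitation, mm/yr
    PET: Grid  # potential evapotranspiration, mm/yr
    AWC: Grid  # plant-available water content, mm
    Z: float = DEFAULT_Z

    def __post_init__(self) -> None:
        if not 0 < self.Z <= 30:
            raise ValueError("Z must lie in (0, 30]")
        assert_aligned(self.P, self.PET, self.AWC)


def omega_grid(AWC: Grid, P: Grid, Z: float = DEFAULT_Z) -> Grid:
    """Budyko landscape parameter omega = Z * AWC / P + 1.25 per cell.

    Cells with non-positive precipitation are flagged nodata; a warning
    reports how many.
    """
    assert_aligned(AWC, P)
    valid = AWC.mask & P.mask & (P.values > 0)
    n_bad = int(np.count_nonzero(AWC.mask & P.mask & ~(P.values > 0)))
    if n_bad:
        warnings.warn(f"{n_bad} cells with non-positive precipitation set to nodata")
    out = np.full(P.shape, P.nodata, dtype=float)
    out[valid] = Z * AWC.values[valid] / P.values[valid] + 1.25
    return Grid(out, cell_size=P.cell_size, origin=P.origin, nodata=P.nodata)


def aet_ratio(PET: Grid, P: Grid, omega: Grid) -> Grid:
    """Evaporative fraction AET/P on [0, 1] from the Budyko curve."""
    assert_aligned(PET, P, omega)
    valid = PET.mask & P.mask & omega.mask & (P.values > 0)
    out = np.full(P.shape, P.nodata, dtype=float)
    r = PET.values[valid] / P.values[valid]
    w = omega.values[valid]
    ratio = 1.0 + r - (1.0 + r**w) ** (1.0 / w)
    out[valid] = np.clip(ratio, 0.0, 1.0)
    return Grid(out, cell_size=P.cell_size, origin=P.origin, nodata=P.nodata)


def water_yield(inputs: WaterYieldInputs) -> Grid:
    """Per-cell annual water yield in mm: (1 - AET/P) * P."""
    omega = omega_grid(inputs.AWC, inputs.P, inputs.Z)
    ratio = aet_ratio(inputs.PET, inputs.P, omega)
    valid = ratio.mask & inputs.P.mask
    out = np.full(ratio.shape, ratio.nodata, dtype=float)
    out[valid] = (1.0 - ratio.values[valid]) * inputs.P.values[valid]
    return Grid(out, cell_size=inputs.P.cell_size, origin=inputs.P.origin, nodata=ratio.nodata)


def total_yield_volume(yield_grid: Grid) -> float:
    """Total yield volume in m^3/yr (1 mm on a 500 m cell = 250 m^3)."""
    cell_area_m2 = yield_grid.cell_size**2
    return float(yield_grid.valid_values().sum() * 1e-3 * cell_area_m2)
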