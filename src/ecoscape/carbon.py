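"""Four-pool carbon stock accounting.

Each land-use class carries per-area densities for four pools (aboveground
biomass, belowground biomass, soil organic carbon, dead organic matter), in
t/hm^2. A cell's stock is its area in hm^2 times the summed density of its
class; a 500 m cell covers 25 hm^2. Stock change between two maps is the
per-cell difference, attributable exactly to from->to class flows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid_io import Grid, LandUseGrid, LookupTable, assert_aligned

__all__ = ["POOL_COLUMNS", "cell_carbon", "total_carbon", "carbon_change"]

POOL_COLUMNS = ("CD_above", "CD_below", "CD_soil", "CD_dead")


def _density_sums(table: LookupTable, codes: set[int]) -> dict[int, float]:
    table.require(codes, POOL_COLUMNS)
    sub = table.frame.loc[sorted(codes), list(POOL_COLUMNS)]
    if (sub < 0).any().any():
        raise ValueError("carbon densities must be non-negative")
    return {int(c): float(s) for c, s in sub.sum(axis=1).items()}


def cell_carbon(landuse: LandUseGrid, table: LookupTable, cell_size: float | None = None) -> Grid:
    """Per-cell carbon stock in tonnes."""
    cell_size = landuse.cell_size if cell_size is None else cell_size
    area_hm2 = cell_size**2 / 1e4
    codes = set(int(c) for c in np.unique(landuse.values[landuse.mask]))
    try:
        dens = _density_sums(table, codes)
    except KeyError as exc:
        raise KeyError(f"carbon density table does not cover the map: {exc}") from exc
    out = np.full(landuse.shape, -9999.0)
    for code, d in dens.items():
        out[landuse.values == code] = area_hm2 * d
    return Grid(out, cell_size=cell_size, origin=landuse.origin, nodata=-9999.0)


def total_carbon(stock_grid: Grid) -> float:
    """Total stock over valid cells, in tonnes."""
    return float(stock_grid.valid_values().sum())


def carbon_change(
    map_a: LandUseGrid, map_b: LandUseGrid, table: LookupTable, cell_size: float | None = None
) -> dict:
    """Stock change from ``map_a`` to ``map_b``.

    Returns ``delta_grid`` (per-cell tonnes, b - a), ``delta_total`` and
    ``flow_breakdown``: a DataFrame attributing the total to from->to class
    pairs (its 'delta_t' column sums to ``delta_total`` exactly).
    """
    assert_aligned(map_a, map_b)
    cell_size = map_a.cell_size if cell_size is None else cell_size
    area_hm2 = cell_size**2 / 1e4
    both = map_a.mask & map_b.mask
    codes = set(int(c) for c in np.unique(map_a.values[both])) | set(
        int(c) for c in np.unique(map_b.values[both])
    )
    dens = _density_sums(table, codes)

    stock_a = cell_carbon(map_a, table, cell_size)
    stock_b = cell_carbon(map_b, table, cell_size)
    delta = np.full(map_a.shape, -9999.0)
    delta[both] = stock_b.values[both] - stock_a.values[both]
    delta_grid = Grid(delta, cell_size=cell_size, origin=map_a.origin, nodata=-9999.0)

    rows = []
    fa, fb = map_a.values[both], map_b.values[both]
    for ca in sorted(codes):
        for cb in sorted(codes):
            n = int(np.count_nonzero((fa == ca) & (fb == cb)))
            if n == 0 or ca == cb:
                continue
            rows.append(
                {
                    "from": ca,
                    "to": cb,
                    "n_cells": n,
                    "delta_t": n * area_hm2 * (dens[cb] - dens[ca]),
                }
            )
    breakdown = pd.DataFrame(rows, columns=["from", "to", "n_cells", "delta_t"])
    return {
        "delta_grid": delta_grid,
        "delta_total": float(delta[both].sum()),
        "flow_breakdown": breakdown,
    }
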