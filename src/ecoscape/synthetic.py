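"""Seeded synthetic landscapes with known statistical structure.

Generates everything the pipeline consumes — driver surfaces, climate/soil
surfaces, lookup tables, and a two-epoch land-use pair — on a canvas that
mimics a monsoon-climate metropolis: a construction core, a cropland ring,
a forested periphery at higher elevation, and a contiguous river corridor.
The default canvas is 150 x 200 cells at 500 m (~7,500 km^2, the order of
magnitude of a large prefecture-level study area), with class proportions
echoing a cropland/forest/construction-dominated structure.

Spatial texture comes from Gaussian-kernel smoothing of white noise;
driver-class association is planted through per-class affinity scores, and
the epoch-1 -> epoch-2 evolution follows a user-specified row-stochastic
transition matrix exactly (up to integer rounding), with conversions placed
preferentially at cells most suited to the destination class. Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid_io import CLASS_ORDER, Grid, LandUseGrid, LookupTable
from .habitat import ThreatSpec
from .markov import largest_remainder_round, validate_transition_matrix

__all__ = ["LandscapeSpec", "generate_drivers", "generate_landuse", "evolve_landuse",
           "generate_tables", "DEFAULT_EPOCH_TRANSITION"]

#: Planted 5-year transition structure mimicking rapid-urbanization change:
#: construction growth fed mainly by forest and cropland, small exchanges
#: elsewhere, construction and unutilized nearly inert.
DEFAULT_EPOCH_TRANSITION = np.array(
    [
        # A      F      G      W      C      U
        [0.955, 0.005, 0.000, 0.005, 0.035, 0.000],  # cropland
        [0.010, 0.925, 0.005, 0.000, 0.060, 0.000],  # forest
        [0.020, 0.030, 0.920, 0.000, 0.030, 0.000],  # grassland
        [0.020, 0.000, 0.000, 0.950, 0.030, 0.000],  # water
        [0.005, 0.000, 0.000, 0.005, 0.990, 0.000],  # construction
        [0.000, 0.000, 0.000, 0.000, 0.000, 1.000],  # unutilized
    ]
)


@dataclasses.dataclass
class LandscapeSpec:
    """Parameters of one synthetic landscape."""

    shape: tuple[int, int] = (150, 200)
    cell_size: float = 500.0
    seed: int = 0
    #: target shares for (cropland, forest, grassland, water, construction,
    #: unutilized); defaults echo a 2020-style structure.
    class_proportions: tuple[float, ...] = (0.27, 0.41, 0.02, 0.08, 0.22, 0.00)
    autocorrelation_length: float = 6.0  # cells
    driver_effect_sizes: Mapping[str, float] = dataclasses.field(default_factory=dict)
    epoch_transition: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_EPOCH_TRANSITION.copy()
    )

    def __post_init__(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.shape != (6,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must be 6 non-negative shares summing to 1")
        self.epoch_transition = validate_transition_matrix(self.epoch_transition)


def _smooth(rng: np.random.Generator, shape, length: float) -> np.ndarray:
    """Zero-mean unit-variance autocorrelated noise field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), length, mode="reflect")
    return (f - f.mean()) / max(f.std(), 1e-12)


def _grid(spec: LandscapeSpec, values: np.ndarray) -> Grid:
    return Grid(values.astype(float), cell_size=spec.cell_size, nodata=-9999.0)


def _distance_to(mask: np.ndarray, cell_size: float) -> np.ndarray:
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask) * cell_size


def _river_path(rng: np.random.Generator, shape) -> np.ndarray:
    """Random-walk polyline from the west to the east edge, buffered 1 cell."""
    nr, nc = shape
    mask = np.zeros(shape, dtype=bool)
    row = int(rng.integers(nr // 3, 2 * nr // 3))
    for col in range(nc):
        row = int(np.clip(row + rng.integers(-1, 2), 1, nr - 2))
        mask[row, col] = True
    return ndimage.binary_dilation(mask, iterations=1)


def generate_drivers(spec: LandscapeSpec) -> dict[str, Grid]:
    """All driver, climate and soil surfaces, mutually aligned.

    Keys: elevation, slope, aspect, dist_city_center, dist_county_center,
    dist_road, dist_railway, dist_water, pop_density, gdp, precipitation,
    pet, awc; plus the internal masks '_river' and '_center' used by the
    land-use generator.
    """
    nr, nc = spec.shape
    if min(nr, nc) < 8:
        raise ValueError("landscape must be at least 8 x 8 cells")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    L = spec.autocorrelation_length
    yy, xx = np.mgrid[0:nr, 0:nc]

    # elevation: smoothed noise plus a ramp rising toward the NE corner
    ramp = (xx / nc + (1 - yy / nr)) / 2.0
    elev = 400.0 * ramp + 120.0 * _smooth(rng, spec.shape, L) + 200.0
    elev = np.maximum(elev, 1.0)

    gy, gx = np.gradient(elev, spec.cell_size)
    slope = np.degrees(np.arctan(np.hypot(gy, gx)))
    aspect = np.degrees(np.arctan2(-gx, gy)) % 360.0

    # point/line features
    center = (int(nr * 0.55 + rng.integers(-3, 4)), int(nc * 0.45 + rng.integers(-3, 4)))
    center_mask = np.zeros(spec.shape, dtype=bool)
    center_mask[center] = True
    county_mask = np.zeros(spec.shape, dtype=bool)
    for _ in range(4):
        county_mask[rng.integers(2, nr - 2), rng.integers(2, nc - 2)] = True

    from skimage.draw import line

    road_mask = np.zeros(spec.shape, dtype=bool)
    for _ in range(3):
        edge = (int(rng.integers(0, nr)), int(rng.choice([0, nc - 1])))
        rr, cc = line(center[0], center[1], edge[0], edge[1])
        road_mask[rr, cc] = True
    rail_mask = np.zeros(spec.shape, dtype=bool)
    for _ in range(2):
        e1 = (0, int(rng.integers(0, nc)))
        e2 = (nr - 1, int(rng.integers(0, nc)))
        rr, cc = line(e1[0], e1[1], e2[0], e2[1])
        rail_mask[rr, cc] = True

    river = _river_path(rng, spec.shape)

    d_center = _distance_to(center_mask, spec.cell_size)
    pop = 8000.0 * np.exp(-d_center / (0.15 * nc * spec.cell_size))
    pop = pop * np.exp(0.3 * _smooth(rng, spec.shape, L)) + 10.0
    gdp = 500.0 * np.exp(-d_center / (0.18 * nc * spec.cell_size))
    gdp = gdp * np.exp(0.3 * _smooth(rng, spec.shape, L)) + 1.0

    precip = 1800.0 - 500.0 * ramp + 120.0 * _smooth(rng, spec.shape, L)
    precip = np.maximum(precip, 600.0)
    pet = 900.0 + 300.0 * ramp + 80.0 * _smooth(rng, spec.shape, L)
    pet = np.maximum(pet, 200.0)
    awc = np.maximum(90.0 + 35.0 * _smooth(rng, spec.shape, L), 10.0)

    out = {
        "elevation": elev,
        "slope": slope,
        "aspect": aspect,
        "dist_city_center": d_center,
        "dist_county_center": _distance_to(county_mask, spec.cell_size),
        "dist_road": _distance_to(road_mask, spec.cell_size),
        "dist_railway": _distance_to(rail_mask, spec.cell_size),
        "dist_water": _distance_to(river, spec.cell_size),
        "pop_density": pop,
        "gdp": gdp,
        "precipitation": precip,
        "pet": pet,
        "awc": awc,
    }
    grids = {k: _grid(spec, v) for k, v in out.items()}
    grids["_river"] = _grid(spec, river.astype(float))
    grids["_center"] = _grid(spec, center_mask.astype(float))
    return grids


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / max(v.std(), 1e-12)


def class_affinities(
    spec: LandscapeSpec, drivers: Mapping[str, Grid], rng: np.random.Generator | None = None
) -> np.ndarray:
    """(6, nrows, ncols) per-class affinity scores over the drivers.

    ``driver_effect_sizes`` entries scale a named driver's contribution to
    every class it enters, letting tests plant a dominant driver.
    """
    eff = dict(spec.driver_effect_sizes)

    def z(name: str) -> np.ndarray:
        return eff.get(name, 1.0) * _zscore(drivers[name].values)

    zd = z("dist_city_center")
    ze = z("elevation")
    zs = z("slope")
    zw = z("dist_water")
    zp = z("pop_density")

    aff = np.empty((6,) + spec.shape)
    aff[0] = -1.2 * (zd - 0.1) ** 2 - 0.5 * zs - 0.3 * ze  # cropland ring
    aff[1] = 1.2 * ze + 0.7 * zd + 0.3 * zs  # forest periphery
    aff[2] = 0.5 * ze + 0.2 * zs  # grassland
    aff[3] = -2.5 * zw - 0.4 * ze  # water near the river
    aff[4] = -1.5 * zd + 0.9 * zp - 0.5 * ze  # construction core
    aff[5] = 0.0  # unutilized: no systematic preference
    if rng is not None:
        L = spec.autocorrelation_length
        for i in range(6):
            aff[i] = aff[i] + 0.6 * _smooth(rng, spec.shape, L / 2)
    return aff


def _assign_quota(scores: np.ndarray, quotas: np.ndarray, n_iter: int = 120) -> np.ndarray:
    """Class index per cell matching quotas via bias-adjusted argmax."""
    n = scores.shape[1]
    target = quotas / n
    bias = np.zeros(scores.shape[0])
    active = quotas > 0
    scores = scores.copy()
    scores[~active] = -np.inf
    assign = np.argmax(scores, axis=0)
    for _ in range(n_iter):
        assign = np.argmax(scores + bias[:, None], axis=0)
        share = np.bincount(assign, minlength=scores.shape[0]) / n
        bias[active] += 0.4 * np.log((target[active] + 1e-9) / (share[active] + 1e-9))
    return assign


def generate_landuse(spec: LandscapeSpec, drivers: Mapping[str, Grid]) -> LandUseGrid:
    """Epoch-1 land-use map with realized shares within ~1 pp of target.

    The river corridor is pre-assigned to water (so the corridor is
    contiguous); remaining cells are distributed by per-class affinity plus
    autocorrelated noise under a quota-matching bias search.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    nr, nc = spec.shape
    n = nr * nc
    props = np.asarray(spec.class_proportions)
    quotas = largest_remainder_round(props * n, total=n)

    aff = class_affinities(spec, drivers, rng).reshape(6, n)
    for i in range(6):
        if quotas[i] > 0 and not np.isfinite(aff[i]).any():
            raise ValueError(f"class {CLASS_ORDER[i]} demanded but has no feasible cells")

    out = np.zeros(n, dtype=np.int32)
    river = drivers["_river"].values.astype(bool).ravel()
    w_quota = int(quotas[3])
    river_cells = np.flatnonzero(river)
    if w_quota > 0 and river_cells.size:
        take = river_cells[np.argsort(-aff[3, river_cells])][: min(w_quota, river_cells.size)]
        out[take] = 4
    placed_w = int(np.count_nonzero(out == 4))

    rest = out == 0
    rest_quotas = quotas.copy()
    rest_quotas[3] = max(0, w_quota - placed_w)
    rest_quotas = largest_remainder_round(
        rest_quotas.astype(float), total=int(rest.sum())
    ) if rest_quotas.sum() != rest.sum() else rest_quotas
    assign = _assign_quota(aff[:, rest], rest_quotas.astype(float))
    out[rest] = np.asarray(CLASS_ORDER, dtype=np.int32)[assign]
    return LandUseGrid(out.reshape(spec.shape), cell_size=spec.cell_size)


def evolve_landuse(
    epoch1: LandUseGrid, spec: LandscapeSpec, drivers: Mapping[str, Grid]
) -> LandUseGrid:
    """Epoch-2 map whose empirical cross-tabulation row-normalizes to
    ``spec.epoch_transition`` up to integer rounding.

    Within each from-class, per-destination conversion counts are fixed by
    largest-remainder rounding of the planted row; the converting cells are
    those with the highest destination affinity (plus seeded Gumbel noise),
    so conversions cluster where the destination class is plausible.
    """
    from .grid_io import assert_aligned

    assert_aligned(epoch1, drivers["elevation"])
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 303]))
    T = spec.epoch_transition
    aff = class_affinities(spec, drivers, None).reshape(6, -1)
    flat1 = epoch1.values.ravel()
    out = flat1.copy()
    idx_of = {c: i for i, c in enumerate(CLASS_ORDER)}

    for f_code in CLASS_ORDER:
        fi = idx_of[f_code]
        cells = np.flatnonzero(flat1 == f_code)
        if cells.size == 0:
            continue
        counts = largest_remainder_round(T[fi] * cells.size, total=cells.size)
        taken = np.zeros(cells.size, dtype=bool)
        dests = sorted(
            (c for c in CLASS_ORDER if c != f_code and counts[idx_of[c]] > 0),
            key=lambda c: -counts[idx_of[c]],
        )
        for d_code in dests:
            need = int(counts[idx_of[d_code]])
            free = np.flatnonzero(~taken)
            score = aff[idx_of[d_code], cells[free]] + rng.gumbel(size=free.size)
            pick = free[np.argsort(-score)][:need]
            out[cells[pick]] = d_code
            taken[pick] = True
    return epoch1.with_values(out.reshape(epoch1.shape))


def generate_tables(seed: int = 0) -> dict:
    """Carbon-density and habitat lookup tables plus the default threat set.

    Densities (t/hm^2) follow the usual ordering forest > cropland ~
    grassland > water ~ construction, with a small seeded jitter; habitat
    suitability is 1 for forest/water and 0 for construction; threats are
    construction (weight 1.0, reach 3 km) and cropland (0.6, 1.5 km).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    base = {
        # code: (above, below, soil, dead)
        1: (12.0, 3.0, 85.0, 2.0),  # cropland
        2: (35.0, 9.0, 120.0, 6.0),  # forest
        3: (8.0, 2.0, 70.0, 1.5),  # grassland
        4: (0.5, 0.1, 25.0, 0.0),  # water
        5: (2.0, 0.5, 30.0, 0.0),  # construction
        6: (1.0, 0.3, 20.0, 0.5),  # unutilized
    }
    rows = []
    for code, pools in base.items():
        jit = 1.0 + 0.05 * rng.standard_normal(4)
        rows.append(
            {"code": code, **dict(zip(("CD_above", "CD_below", "CD_soil", "CD_dead"),
                                      np.maximum(np.array(pools) * jit, 0.0)))}
        )
    carbon = LookupTable(pd.DataFrame(rows))

    habitat = LookupTable(
        pd.DataFrame(
            {
                "code": list(CLASS_ORDER),
                "H": [0.4, 1.0, 0.7, 1.0, 0.0, 0.1],
                "S_construction": [0.5, 0.8, 0.6, 0.7, 0.0, 0.2],
                "S_cropland": [0.0, 0.6, 0.4, 0.5, 0.0, 0.1],
            }
        )
    )
    threats = [
        ThreatSpec("construction", source_classes=(5,), weight=1.0, max_distance=3000.0),
        ThreatSpec("cropland", source_classes=(1,), weight=0.6, max_distance=1500.0),
    ]
    return {"carbon_density": carbon, "habitat": habitat, "threats": threats}
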