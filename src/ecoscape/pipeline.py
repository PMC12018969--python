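"""End-to-end orchestration and reporting.

Area/change accounting uses the reporting conventions of land-change
studies: per-class areas in km^2, shares as percentages of the study-area
total rounded half-up to two decimals, and change tables as from->to flow
matrices in km^2 whose marginals give per-class deltas. The study-area
total may be overridden by an externally fixed constant (shares in
published tables are often computed against the administrative total rather
than the raster's valid area).

:func:`run_pipeline` binds the stages together on a synthetic landscape:
two-epoch generation, transition estimation, scenario demand projection, CA
allocation, the three ecosystem services per map, and (optionally)
geographical-detector driver attribution on the change indicator.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import ca, carbon, geodetector, habitat, markov, synthetic, water
from .grid_io import CLASS_ORDER, LAND_USE_CLASSES, LandUseGrid, write_raster

__all__ = [
    "area_stats",
    "share_table",
    "change_table",
    "deltas_from_areas",
    "reconcile_demand",
    "RunConfig",
    "run_pipeline",
    "zonal_statistics",
]

logger = logging.getLogger("ecoscape")


def _round2(x: float) -> float:
    """Round half-up to 2 decimals (the convention of printed area tables)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def share_table(areas_km2: Mapping[int, float], total_km2: float | None = None) -> pd.DataFrame:
    """Shares (%) of per-class areas against a total, rounded half-up to 2 dp."""
    total = float(total_km2) if total_km2 is not None else float(sum(areas_km2.values()))
    rows = []
    for code in sorted(areas_km2):
        area = float(areas_km2[code])
        rows.append(
            {
                "code": code,
                "name": LAND_USE_CLASSES.get(code, str(code)),
                "area_km2": _round2(area),
                "share_pct": _round2(100.0 * area / total),
            }
        )
    return pd.DataFrame(rows).set_index("code")


def area_stats(
    landuse: LandUseGrid,
    cell_size: float | None = None,
    total_area_km2: float | None = None,
) -> pd.DataFrame:
    """Per-class area (km^2) and share (%) of a land-use map."""
    cell_size = landuse.cell_size if cell_size is None else cell_size
    cell_km2 = cell_size**2 / 1e6
    areas = {c: n * cell_km2 for c, n in landuse.class_counts().items()}
    return share_table(areas, total_area_km2)


def deltas_from_areas(
    earlier: Mapping[int, float], later: Mapping[int, float]
) -> dict[int, float]:
    """Per-class area change (later - earlier), km^2."""
    return {c: float(later[c]) - float(earlier[c]) for c in sorted(earlier)}


def change_table(
    map_earlier: LandUseGrid, map_later: LandUseGrid, cell_size: float | None = None
) -> dict:
    """Cross-tabulated from->to flows (km^2) and per-class deltas."""
    from .grid_io import assert_aligned

    assert_aligned(map_earlier, map_later)
    cell_size = map_earlier.cell_size if cell_size is None else cell_size
    cell_km2 = cell_size**2 / 1e6
    both = map_earlier.mask & map_later.mask
    a, b = map_earlier.values[both], map_later.values[both]
    codes = list(CLASS_ORDER)
    flow = pd.DataFrame(0.0, index=codes, columns=codes)
    for ca_ in codes:
        sel = a == ca_
        if not sel.any():
            continue
        for cb in codes:
            n = int(np.count_nonzero(b[sel] == cb))
            if n:
                flow.loc[ca_, cb] = n * cell_km2
    deltas = {c: float(flow[c].sum() - flow.loc[c].sum()) for c in codes}
    return {"flow_km2": flow, "delta_km2": deltas}


def reconcile_demand(
    demand: np.ndarray, counts: np.ndarray, restricted: Sequence[int]
) -> np.ndarray:
    """Clamp demand of frozen classes to at least their current counts.

    Frozen (RDA) cells cannot convert away, so demand below the frozen
    count is unreachable; the surplus is taken from the largest
    non-restricted demands by largest remainder so the total is conserved.
    """
    demand = np.asarray(demand, dtype=float).copy()
    idx = {c: i for i, c in enumerate(CLASS_ORDER)}
    r_idx = [idx[c] for c in restricted]
    free = [i for i in range(len(CLASS_ORDER)) if i not in r_idx]
    total = int(round(demand.sum()))
    for i in r_idx:
        demand[i] = max(demand[i], counts[i])
    excess = demand.sum() - total
    if excess > 0 and free:
        free_total = demand[free].sum()
        if free_total > 0:
            demand[free] *= (free_total - excess) / free_total
    out = markov.largest_remainder_round(demand, total=total)
    # rounding must not push a frozen class back below its floor
    for i in r_idx:
        while out[i] < counts[i]:
            j = int(np.argmax(out[free]))
            out[free[j]] -= 1
            out[i] += 1
    return out


def zonal_statistics(value_grid, zone_grid) -> pd.DataFrame:
    """Mean/sum/count of a value raster per integer zone."""
    ok = value_grid.mask & zone_grid.mask
    zones = zone_grid.values[ok].astype(int)
    vals = value_grid.values[ok]
    rows = []
    for z in np.unique(zones):
        sel = zones == z
        rows.append(
            {"zone": int(z), "n": int(sel.sum()), "mean": float(vals[sel].mean()),
             "sum": float(vals[sel].sum())}
        )
    return pd.DataFrame(rows).set_index("zone")


@dataclasses.dataclass
class RunConfig:
    """Everything one end-to-end synthetic run needs."""

    seed: int = 0
    shape: tuple[int, int] = (150, 200)
    cell_size: float = 500.0
    scenarios: tuple[str, ...] = ("S1", "S2", "S3")
    n_steps: int = 3  # 5-year steps: a 2020-analogue projected to 2035
    model_kind: str = "multinomial-logistic"
    mode: str = "roulette"
    z_constant: float = water.DEFAULT_Z
    do_services: bool = True
    do_detect: bool = False
    n_permutations: int = 199
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shape"] = list(self.shape)
        d["scenarios"] = list(self.scenarios)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        if "scenarios" in d:
            d["scenarios"] = tuple(d["scenarios"])
        return cls(**d)


_DETECT_DRIVERS = (
    "elevation", "slope", "aspect", "dist_city_center", "dist_county_center",
    "dist_road", "dist_railway", "dist_water", "pop_density", "gdp",
    "precipitation",
)

_FIT_DRIVERS = (
    "elevation", "slope", "dist_city_center", "dist_county_center",
    "dist_road", "dist_railway", "dist_water", "pop_density", "gdp",
)


def _services_for(
    map_: LandUseGrid, drivers, tables, z_constant: float, k: float | None = None
) -> dict:
    wy = water.water_yield(
        water.WaterYieldInputs(
            P=drivers["precipitation"], PET=drivers["pet"], AWC=drivers["awc"], Z=z_constant
        )
    )
    D = habitat.degradation(map_, tables["threats"], tables["habitat"])
    # a half-saturation constant fixed across the run's maps keeps quality
    # comparable between scenarios
    Q = habitat.quality(map_, D, tables["habitat"], habitat.QualityParams(half_saturation=k))
    stock = carbon.cell_carbon(map_, tables["carbon_density"])
    return {
        "water_yield": wy,
        "water_total_m3": water.total_yield_volume(wy),
        "degradation": D,
        "quality": Q,
        "quality_mean": float(Q.valid_values().mean()),
        "carbon": stock,
        "carbon_total_t": carbon.total_carbon(stock),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Simulate -> services -> (detect) on one seeded synthetic landscape.

    Returns a results dictionary; when ``config.out_dir`` is set, also
    writes rasters (GeoTIFF), area/change CSVs, a machine-readable summary
    and a log file. Deterministic given (config, seed).
    """
    t0 = datetime.datetime.now()
    spec = synthetic.LandscapeSpec(
        shape=config.shape, cell_size=config.cell_size, seed=config.seed
    )
    logger.info("stage=synth seed=%d shape=%s", config.seed, config.shape)
    drivers = synthetic.generate_drivers(spec)
    epoch1 = synthetic.generate_landuse(spec, drivers)
    epoch2 = synthetic.evolve_landuse(epoch1, spec, drivers)
    tables = synthetic.generate_tables(config.seed)

    T = markov.estimate_transition(epoch1, epoch2)
    counts2 = np.array([epoch2.class_counts()[c] for c in CLASS_ORDER])
    scen_all = markov.builtin_scenarios()

    fit = ca.fit_suitability(
        epoch2,
        {k: drivers[k] for k in _FIT_DRIVERS},
        model_kind=config.model_kind,
        seed=config.seed,
    )
    suit = ca.predict_suitability(fit, drivers)

    results: dict = {
        "config": config.to_dict(),
        "transition": T,
        "baseline": {"map": epoch2, "area": area_stats(epoch2)},
        "scenarios": {},
    }
    k_run: float | None = None
    if config.do_services:
        # auto-k on the baseline map; the same k then scores every scenario
        # map so quality is comparable across scenarios
        base_sv = _services_for(epoch2, drivers, tables, config.z_constant)
        k_run = habitat.half_saturation_default(base_sv["degradation"])
        results["baseline"]["services"] = base_sv

    for name in config.scenarios:
        sc = scen_all[name]
        logger.info("stage=scenario name=%s", name)
        Ts = markov.apply_scenario(T, sc)
        demand = markov.project_demand(counts2, Ts, config.n_steps)
        demand = reconcile_demand(demand, counts2, sorted(sc.restricted_classes))
        sim, report = ca.allocate(
            epoch2, suit, sc, demand, seed=config.seed, mode=config.mode
        )
        entry: dict = {
            "map": sim,
            "demand": demand,
            "report": report,
            "area": area_stats(sim),
            "change": change_table(epoch2, sim),
        }
        if config.do_services:
            entry["services"] = _services_for(sim, drivers, tables, config.z_constant, k=k_run)
        results["scenarios"][name] = entry

    if config.do_detect:
        logger.info("stage=detect")
        sim0 = results["scenarios"][config.scenarios[0]]["map"]
        response = np.where(
            epoch2.mask, (epoch2.values != sim0.values).astype(float), np.nan
        ).ravel()
        factors = {}
        for dname in _DETECT_DRIVERS:
            strata, qres = geodetector.optimal_discretize(
                drivers[dname], response, seed=config.seed
            )
            qres.p_value = geodetector.q_significance(
                response, strata, n_permutations=config.n_permutations, seed=config.seed
            )
            factors[dname] = {"q": qres.q, "p": qres.p_value, "strata": strata,
                              "spec": qres.spec}
        results["detect"] = factors

    if config.out_dir is not None:
        _write_outputs(Path(config.out_dir), config, results, t0)
    return results


def _write_outputs(out: Path, config: RunConfig, results: dict, t0) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_raster(results["baseline"]["map"], out / "landuse_baseline.tif")
    results["baseline"]["area"].to_csv(out / "area_baseline.csv")
    cfg_dict = config.to_dict()
    cfg_dict.pop("out_dir", None)  # paths must not break summary determinism
    summary: dict = {"config": cfg_dict, "baseline": {}}
    if "services" in results["baseline"]:
        sv = results["baseline"]["services"]
        summary["baseline"] = {
            "water_total_m3": sv["water_total_m3"],
            "quality_mean": sv["quality_mean"],
            "carbon_total_t": sv["carbon_total_t"],
        }
    for name, entry in results["scenarios"].items():
        write_raster(entry["map"], out / f"landuse_{name}.tif")
        entry["area"].to_csv(out / f"area_{name}.csv")
        entry["change"]["flow_km2"].to_csv(out / f"flows_{name}.csv")
        s = {
            "iterations": entry["report"].iterations,
            "conversions": entry["report"].n_conversions,
            "residuals": entry["report"].residuals,
        }
        if "services" in entry:
            s.update(
                water_total_m3=entry["services"]["water_total_m3"],
                quality_mean=entry["services"]["quality_mean"],
                carbon_total_t=entry["services"]["carbon_total_t"],
            )
        summary[name] = s
    if "detect" in results:
        pd.DataFrame(
            [
                {"driver": d, "q": v["q"], "p": v["p"],
                 "method": v["spec"].method, "n_classes": v["spec"].n_classes}
                for d, v in results["detect"].items()
            ]
        ).sort_values("q", ascending=False).to_csv(out / "factor_q.csv", index=False)
    (out / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=True))
    dur = (datetime.datetime.now() - t0).total_seconds()
    with open(out / "run.log", "a") as fh:
        fh.write(
            f"{datetime.datetime.now().isoformat()} seed={config.seed} "
            f"scenarios={','.join(config.scenarios)} duration_s={dur:.1f}\n"
        )
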