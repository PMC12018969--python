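"""Suitability estimation and cellular-automaton demand allocation.

The allocation engine converts cells between classes until per-class counts
meet a projected demand, under scenario constraints. Each candidate
conversion of a cell to class t is scored as

    score = P_occ(t | drivers) * (neighborhood_t + delta) * inertia_t

where P_occ comes from a per-class occurrence-probability model fitted on an
observed map (multinomial logistic by default, a shallow neural network
optionally), neighborhood_t is the weighted same-class density in a Moore
window, inertia_t a self-adaptive coefficient that rises while a class stays
under-supplied, and delta a small floor (0.01) letting classes with zero
neighborhood weight or no local presence still seed new cells. Conversions
only ever run from over-supplied to under-supplied classes and only where
the scenario's cost matrix permits them; cells of restricted (RDA) classes
are frozen. ``greedy`` mode takes candidates in strict score order and is
fully deterministic; ``roulette`` mode samples candidates with probability
proportional to score (Gumbel top-k), reproducibly under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
from scipy import ndimage

from .grid_io import CLASS_ORDER, Grid, LandUseGrid, assert_aligned
from .markov import ScenarioConfig

__all__ = [
    "SuitabilityModel",
    "AllocationError",
    "AllocationReport",
    "fit_suitability",
    "predict_suitability",
    "neighborhood_effect",
    "allocate",
]

NEIGHBORHOOD_FLOOR = 0.01


class AllocationError(RuntimeError):
    """Demand could not be met; carries per-class residual gaps."""

    def __init__(self, message: str, residuals: dict[int, int]):
        super().__init__(f"{message}; residual gaps (demand - count): {residuals}")
        self.residuals = residuals


@dataclasses.dataclass
class SuitabilityModel:
    """A fitted per-class occurrence-probability model."""

    estimator: object
    scaler: object
    driver_names: tuple[str, ...]
    classes: tuple[int, ...]  # codes the estimator knows, estimator order
    model_kind: str


def _driver_matrix(drivers: Mapping[str, Grid], names, mask: np.ndarray) -> np.ndarray:
    cols = []
    for name in names:
        if name not in drivers:
            raise KeyError(f"missing driver {name!r}")
        cols.append(drivers[name].values[mask].astype(float))
    return np.column_stack(cols)


def fit_suitability(
    landuse: LandUseGrid,
    drivers: Mapping[str, Grid],
    model_kind: str = "multinomial-logistic",
    seed: int = 0,
    sample_per_class: int = 2000,
) -> SuitabilityModel:
    """Fit the occurrence-probability model on a balanced, seeded sample.

    Classes present with fewer than 10 cells raise an error (the fit would
    be meaningless); classes absent from the map are simply not modelled and
    later receive zero probability.
    """
    if model_kind not in ("multinomial-logistic", "shallow-neural"):
        raise ValueError("model_kind must be 'multinomial-logistic' or 'shallow-neural'")
    names = tuple(sorted(drivers))
    assert_aligned(landuse, *[drivers[n] for n in names])
    rng = np.random.default_rng(seed)
    mask = landuse.mask
    codes = landuse.values[mask]
    rows = np.flatnonzero(mask.ravel())

    sel: list[np.ndarray] = []
    for code in CLASS_ORDER:
        idx = rows[codes == code]
        if idx.size == 0:
            continue
        if idx.size < 10:
            raise ValueError(
                f"class {code} has only {idx.size} cells; need >= 10 to fit suitability"
            )
        take = min(idx.size, sample_per_class)
        sel.append(rng.choice(idx, size=take, replace=False))
    sample = np.concatenate(sel)
    flat_mask = np.zeros(landuse.values.size, dtype=bool)
    flat_mask[sample] = True
    sample_mask = flat_mask.reshape(landuse.shape)
    X = _driver_matrix(drivers, names, sample_mask)
    y = landuse.values[sample_mask]

    from sklearn.preprocessing import StandardScaler

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    if model_kind == "multinomial-logistic":
        from sklearn.linear_model import LogisticRegression

        est = LogisticRegression(max_iter=1000, C=1.0)
    else:
        from sklearn.neural_network import MLPClassifier

        est = MLPClassifier(
            hidden_layer_sizes=(12,), max_iter=500, random_state=seed, early_stopping=False
        )
    est.fit(Xs, y)
    return SuitabilityModel(
        estimator=est,
        scaler=scaler,
        driver_names=names,
        classes=tuple(int(c) for c in est.classes_),
        model_kind=model_kind,
    )


def predict_suitability(model: SuitabilityModel, drivers: Mapping[str, Grid]) -> dict[int, Grid]:
    """Per-class occurrence-probability surfaces summing to 1 per valid cell.

    Valid cells are those valid in every driver; classes unknown to the
    model get an all-zero surface.
    """
    missing = [n for n in model.driver_names if n not in drivers]
    if missing:
        raise KeyError(f"missing driver(s) {missing} required by the fitted model")
    ref = drivers[model.driver_names[0]]
    mask = np.ones(ref.shape, dtype=bool)
    for name in model.driver_names:
        mask &= drivers[name].mask
    X = model.scaler.transform(_driver_matrix(drivers, model.driver_names, mask))
    proba = model.estimator.predict_proba(X)
    proba = proba / proba.sum(axis=1, keepdims=True)
    out: dict[int, Grid] = {}
    for code in CLASS_ORDER:
        surface = np.full(ref.shape, -9999.0)
        if code in model.classes:
            surface[mask] = proba[:, model.classes.index(code)]
        else:
            surface[mask] = 0.0
        out[code] = Grid(surface, cell_size=ref.cell_size, origin=ref.origin, nodata=-9999.0)
    return out


def neighborhood_effect(
    landuse: LandUseGrid, target_class: int, window: int = 3, weights: Mapping[int, float] | float = 1.0
) -> Grid:
    """Weighted same-class density in a (window x window) Moore neighborhood.

    Per cell: weight * (# target-class neighbors, centre excluded) / (window^2 - 1).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    w = weights[target_class] if isinstance(weights, Mapping) else float(weights)
    ind = (landuse.values == target_class).astype(float)
    kernel = np.ones((window, window))
    kernel[window // 2, window // 2] = 0.0
    dens = ndimage.correlate(ind, kernel, mode="constant", cval=0.0) / (window**2 - 1)
    return Grid(w * dens, cell_size=landuse.cell_size, origin=landuse.origin, nodata=-9999.0)


def _class_counts(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    v = values[mask]
    return np.array([np.count_nonzero(v == c) for c in CLASS_ORDER])


@dataclasses.dataclass
class AllocationReport:
    iterations: int
    n_conversions: int
    residuals: dict[int, int]  # code -> demand - final count
    converged: bool


def allocate(
    landuse_t: LandUseGrid,
    suitability: Mapping[int, Grid],
    scenario: ScenarioConfig,
    demand: np.ndarray,
    seed: int = 0,
    mode: str = "roulette",
    max_iter: int = 500,
    budget_frac: float = 0.01,
    tol_frac: float = 0.005,
    window: int = 3,
) -> tuple[LandUseGrid, AllocationReport]:
    """Iteratively convert cells until class counts meet ``demand``.

    ``demand`` is per-class target cell counts (legend order) summing to the
    number of valid cells. At most ``budget_frac`` of cells convert per
    iteration. Success requires every residual gap within ``tol_frac`` of
    the total cell count; a stalled run beyond tolerance raises
    :class:`AllocationError` with per-class residuals.
    """
    if mode not in ("roulette", "greedy"):
        raise ValueError("mode must be 'roulette' or 'greedy'")
    demand = np.asarray(demand, dtype=int)
    mask = landuse_t.mask
    n_valid = int(mask.sum())
    if demand.shape != (len(CLASS_ORDER),) or demand.sum() != n_valid:
        raise ValueError(f"demand must be 6 counts summing to {n_valid}")
    rng = np.random.default_rng(seed)
    code_idx = {c: i for i, c in enumerate(CLASS_ORDER)}

    cur = landuse_t.values.copy()
    frozen = np.zeros(cur.shape, dtype=bool)
    for code in scenario.restricted_classes:
        frozen |= cur == code
    frozen &= mask

    counts = _class_counts(cur, mask)
    gap = demand - counts
    inertia = np.ones(len(CLASS_ORDER))
    prev_sign = np.zeros(len(CLASS_ORDER))
    budget = max(1, int(round(budget_frac * n_valid)))
    tol_cells = int(np.ceil(tol_frac * n_valid))
    total_conversions = 0
    it = 0

    while it < max_iter and np.abs(gap).max() > 0:
        it += 1
        under = [c for c in CLASS_ORDER if gap[code_idx[c]] > 0]
        over = [c for c in CLASS_ORDER if gap[code_idx[c]] < 0]
        if not under or not over:
            break

        cand_scores: list[np.ndarray] = []
        cand_cells: list[np.ndarray] = []
        cand_targets: list[np.ndarray] = []
        for t in under:
            ti = code_idx[t]
            donors = [f for f in over if scenario.cost_matrix[code_idx[f], ti] == 1 and f != t]
            if not donors:
                continue
            eligible = mask & ~frozen & np.isin(cur, donors)
            if not eligible.any():
                continue
            lu_now = landuse_t.with_values(cur)
            neigh = neighborhood_effect(lu_now, t, window, scenario.neighborhood_weights)
            score = (
                suitability[t].values * (neigh.values + NEIGHBORHOOD_FLOOR) * inertia[ti]
            )
            cells = np.flatnonzero(eligible.ravel())
            cand_scores.append(score.ravel()[cells])
            cand_cells.append(cells)
            cand_targets.append(np.full(cells.size, ti))
        if not cand_scores:
            break
        scores = np.concatenate(cand_scores)
        cells = np.concatenate(cand_cells)
        targets = np.concatenate(cand_targets)

        if mode == "greedy":
            order = np.lexsort((cells, -scores))
        else:
            # Gumbel top-k == sampling without replacement w.p. proportional
            # to score
            with np.errstate(divide="ignore"):
                keys = np.log(np.maximum(scores, 1e-300)) + rng.gumbel(size=scores.size)
            order = np.argsort(-keys, kind="stable")

        flat = cur.ravel()
        converted_this_iter = np.zeros(flat.size, dtype=bool)
        n_changed = 0
        remaining = gap.copy()
        for k in order:
            if n_changed >= budget:
                break
            cell, ti = cells[k], targets[k]
            if converted_this_iter[cell]:
                continue
            fi = code_idx[int(flat[cell])]
            if remaining[ti] <= 0 or remaining[fi] >= 0:
                continue
            flat[cell] = CLASS_ORDER[ti]
            converted_this_iter[cell] = True
            remaining[ti] -= 1
            remaining[fi] += 1
            n_changed += 1
        gap = remaining
        total_conversions += n_changed
        if n_changed == 0:
            break

        # self-adaptive inertia: amplify persistently under-supplied classes
        sign = np.sign(gap)
        for i in range(len(CLASS_ORDER)):
            if sign[i] != 0 and sign[i] == prev_sign[i]:
                factor = 1.0 + abs(gap[i]) / max(demand[i], 1)
                inertia[i] = inertia[i] * factor if gap[i] > 0 else inertia[i] / factor
                inertia[i] = float(np.clip(inertia[i], 0.1, 10.0))
        prev_sign = sign

    residuals = {c: int(gap[code_idx[c]]) for c in CLASS_ORDER}
    converged = int(np.abs(gap).max()) <= tol_cells
    if not converged:
        raise AllocationError("allocation stalled before meeting demand", residuals)
    out = landuse_t.with_values(cur)
    report = AllocationReport(
        iterations=it, n_conversions=total_conversions, residuals=residuals, converged=converged
    )
    return out, report
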