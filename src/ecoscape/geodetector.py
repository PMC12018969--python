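"""Geographical detector: q-statistic, OPGD discretization, interactions.

The factor detector measures how much of a response's spatial variance a
categorical stratification explains:

    q = 1 - SSW / SST,   SSW = sum_h N_h * sigma_h^2,   SST = N * sigma^2

with population variances throughout, so SSW and SST are plain sums of
squared deviations and q equals the R^2 of a one-way ANOVA. For continuous
drivers, the optimal-parameters variant (OPGD) searches discretization
method x number of classes and keeps the stratification with maximal q.
The interaction detector evaluates q on the overlay (Cartesian product) of
two stratifications and classifies the result into the five standard
enhancement/weakening categories.

Strata are passed as integer label arrays aligned with the response grid;
labels < 1 mark cells excluded from the analysis.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .grid_io import Grid

__all__ = [
    "DiscretizationSpec",
    "QResult",
    "factor_q",
    "q_significance",
    "discretize",
    "optimal_discretize",
    "interaction_q",
    "classify_interaction",
    "DEFAULT_CANDIDATES",
]

_METHODS = ("equal-interval", "quantile", "natural-breaks", "geometric")


@dataclasses.dataclass(frozen=True)
class DiscretizationSpec:
    method: str
    n_classes: int

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


#: OPGD default search space: 4 methods x 3..8 classes.
DEFAULT_CANDIDATES: tuple[DiscretizationSpec, ...] = tuple(
    DiscretizationSpec(m, n) for m in _METHODS for n in range(3, 9)
)


@dataclasses.dataclass
class QResult:
    q: float
    ssw: float
    sst: float
    n: int
    n_strata: int
    p_value: float | None = None
    spec: DiscretizationSpec | None = None


def _as_array(response) -> np.ndarray:
    if isinstance(response, Grid):
        return np.where(response.mask, response.values, np.nan).ravel()
    return np.asarray(response, dtype=float).ravel()


def _as_labels(strata) -> np.ndarray:
    if isinstance(strata, Grid):
        lab = np.where(strata.mask, strata.values, 0)
        return np.asarray(lab, dtype=int).ravel()
    return np.asarray(strata, dtype=int).ravel()


def _prepare(response, strata) -> tuple[np.ndarray, np.ndarray]:
    y = _as_array(response)
    lab = _as_labels(strata)
    if y.shape != lab.shape:
        raise ValueError("response and strata are not aligned")
    ok = np.isfinite(y) & (lab >= 1)
    y, lab = y[ok], lab[ok]
    if y.size < 2:
        raise ValueError("need at least two valid cells")
    return y, lab


def _q_from_arrays(y: np.ndarray, lab: np.ndarray) -> tuple[float, float, float]:
    """(q, SSW, SST) with strata encoded as consecutive ints >= 0."""
    sst = float(np.sum((y - y.mean()) ** 2))
    if lab.max() == lab.min():  # single stratum: SSW == SST by definition
        return 0.0, sst, sst
    n_h = np.bincount(lab)
    sums = np.bincount(lab, weights=y)
    sqs = np.bincount(lab, weights=y * y)
    nz = n_h > 0
    ssw = float(np.sum(sqs[nz] - sums[nz] ** 2 / n_h[nz]))
    ssw = max(ssw, 0.0)
    return 1.0 - ssw / sst, ssw, sst


def factor_q(response, strata) -> QResult:
    """Explanatory power q of a stratification for a response.

    Raises if the response is constant (SST = 0).
    """
    y, lab = _prepare(response, strata)
    _, dense = np.unique(lab, return_inverse=True)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("response is constant; q is undefined")
    q, ssw, sst = _q_from_arrays(y, dense)
    return QResult(q=q, ssw=ssw, sst=sst, n=y.size, n_strata=int(dense.max()) + 1)


def q_significance(
    response,
    strata,
    n_permutations: int = 999,
    seed: int = 0,
    method: str = "permutation",
) -> float:
    """p-value for the observed q.

    ``permutation`` (default) shuffles response values over cells and
    recomputes q; the p-value is ``(1 + #{q* >= q_obs}) / (1 + B)``.
    ``analytic`` uses the non-central-F approximation.
    """
    y, lab = _prepare(response, strata)
    import warnings

    if y.size < 30:
        warnings.warn(f"only {y.size} cells; the permutation p-value may be coarse")
    _, dense = np.unique(lab, return_inverse=True)
    q_obs, _, _ = _q_from_arrays(y, dense)
    if method == "analytic":
        # F test of the equivalent one-way ANOVA; the q -> F transform is
        # F = (N-L)/(L-1) * q/(1-q)
        L = int(dense.max()) + 1
        n = y.size
        if L < 2:
            return 1.0
        if q_obs >= 1.0:
            return 0.0
        f_stat = (n - L) / (L - 1) * q_obs / (1.0 - q_obs)
        return float(stats.f.sf(f_stat, L - 1, n - L))
    if method != "permutation":
        raise ValueError("method must be 'permutation' or 'analytic'")
    rng = np.random.default_rng(seed)
    exceed = 0
    yp = y.copy()
    for _ in range(n_permutations):
        rng.shuffle(yp)
        q_star, _, _ = _q_from_arrays(yp, dense)
        if q_star >= q_obs - 1e-12:
            exceed += 1
    return (1 + exceed) / (1 + n_permutations)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------


def _breaks(values: np.ndarray, spec: DiscretizationSpec, seed: int = 0) -> np.ndarray:
    lo, hi = values.min(), values.max()
    k = spec.n_classes
    if spec.method == "equal-interval":
        return np.linspace(lo, hi, k + 1)[1:-1]
    if spec.method == "quantile":
        return np.quantile(values, np.linspace(0, 1, k + 1)[1:-1])
    if spec.method == "geometric":
        # geometric progression of break positions on the shifted range
        shift = 1.0 - lo
        return np.exp(np.linspace(np.log(lo + shift), np.log(hi + shift), k + 1)[1:-1]) - shift
    # natural-breaks: 1-D k-means (Lloyd's on sorted data, deterministic init)
    from sklearn.cluster import KMeans

    uniq = np.unique(values)
    if uniq.size <= k:
        return (uniq[:-1] + uniq[1:]) / 2.0
    km = KMeans(n_clusters=k, n_init=4, random_state=seed)
    km.fit(values.reshape(-1, 1))
    centers = np.sort(km.cluster_centers_.ravel())
    return (centers[:-1] + centers[1:]) / 2.0


def discretize(driver_grid: Grid, spec: DiscretizationSpec, seed: int = 0) -> np.ndarray:
    """Integer stratum labels (1..L) for a continuous driver; 0 = nodata."""
    vals = driver_grid.values
    ok = driver_grid.mask & np.isfinite(vals)
    breaks = _breaks(vals[ok].astype(float), spec, seed)
    lab = np.zeros(vals.shape, dtype=int)
    lab[ok] = np.searchsorted(breaks, vals[ok], side="right") + 1
    return lab


def optimal_discretize(
    driver_grid: Grid,
    response,
    candidates: Sequence[DiscretizationSpec] = DEFAULT_CANDIDATES,
    seed: int = 0,
) -> tuple[np.ndarray, QResult]:
    """OPGD search: the candidate stratification with maximal q.

    Candidates yielding an empty stratum are skipped. Ties break toward
    fewer classes, then candidate order.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    best: tuple[float, int, int] | None = None
    best_out: tuple[np.ndarray, QResult] | None = None
    for i, spec in enumerate(candidates):
        lab = discretize(driver_grid, spec, seed)
        used = lab[lab >= 1]
        if used.size == 0 or np.unique(used).size < spec.n_classes:
            continue  # empty stratum; skip this candidate
        res = factor_q(response, lab)
        res.spec = spec
        key = (-res.q, spec.n_classes, i)
        if best is None or key < best:
            best = key
            best_out = (lab, res)
    if best_out is None:
        raise ValueError("every discretization candidate produced empty strata")
    return best_out


# ---------------------------------------------------------------------------
# Interaction detector
# ---------------------------------------------------------------------------

CATEGORIES = (
    "Weaken, nonlinear",
    "Weaken, univariate",
    "Enhance, bivariate",
    "Independent",
    "Enhance, nonlinear",
)


def classify_interaction(q_a: float, q_b: float, q_ab: float, tol: float = 1e-9) -> str:
    """The five-way interaction category for (q_a, q_b, q_ab)."""
    lo, hi = min(q_a, q_b), max(q_a, q_b)
    s = q_a + q_b
    if abs(q_ab - s) <= tol:
        return "Independent"
    if q_ab > s:
        return "Enhance, nonlinear"
    if q_ab > hi:
        return "Enhance, bivariate"
    if q_ab >= lo:
        return "Weaken, univariate"
    return "Weaken, nonlinear"


def interaction_q(response, strata_a, strata_b) -> dict:
    """q of the overlay of two stratifications plus its category.

    The overlay assigns one stratum to every distinct (a, b) label pair.
    """
    y_a = _as_labels(strata_a)
    y_b = _as_labels(strata_b)
    if y_a.shape != y_b.shape:
        raise ValueError("strata are not aligned")
    both = (y_a >= 1) & (y_b >= 1)
    overlay = np.zeros(y_a.shape, dtype=int)
    pairs = y_a[both] * (y_b.max() + 1) + y_b[both]
    _, dense = np.unique(pairs, return_inverse=True)
    overlay[both] = dense + 1

    res_a = factor_q(response, strata_a)
    res_b = factor_q(response, strata_b)
    yv = _as_array(response)
    ok = np.isfinite(yv) & both
    if np.unique(overlay[ok]).size >= ok.sum():
        raise ValueError(
            "overlay has one stratum per cell; use a coarser discretization"
        )
    res_ab = factor_q(response, overlay)
    return {
        "q_a": res_a.q,
        "q_b": res_b.q,
        "q_ab": res_ab.q,
        "category": classify_interaction(res_a.q, res_b.q, res_ab.q),
    }
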