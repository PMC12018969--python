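"""Markov transition estimation, demand projection and scenario rule sets.

The transition matrix is estimated from a two-epoch pair of land-use maps by
cross-tabulating paired cells; per-class demand at the horizon follows from
multiplying current class counts by powers of the (row-stochastic) matrix.
One matrix step corresponds to the 5-year calibration interval, so a
2020-style map projected to a 2035-style horizon uses ``n_steps=3``.

Three scenario rule sets ship as data: natural development (S1), ecological
protection (S2) and sustainable development (S3). Each combines a binary
conversion-cost matrix (rows = from-class, columns = to-class, legend order
A, F, G, W, C, U), per-class neighborhood weights, restricted ("RDA")
classes whose cells are frozen during allocation, and multiplicative
transition-probability modifiers.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .grid_io import CLASS_LETTERS, CLASS_ORDER, LandUseGrid

__all__ = [
    "ScenarioConfig",
    "estimate_transition",
    "project_demand",
    "apply_scenario",
    "builtin_scenarios",
    "largest_remainder_round",
    "validate_transition_matrix",
]

N_CLASSES = len(CLASS_ORDER)
_CODE_TO_IDX = {c: i for i, c in enumerate(CLASS_ORDER)}


def validate_transition_matrix(matrix: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (N_CLASSES, N_CLASSES):
        raise ValueError(f"transition matrix must be {N_CLASSES}x{N_CLASSES}")
    if (matrix < -tol).any() or (matrix > 1 + tol).any():
        raise ValueError("transition probabilities must lie in [0, 1]")
    rows = matrix.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > tol):
        bad = int(np.argmax(np.abs(rows - 1.0)))
        raise ValueError(f"row {bad} sums to {rows[bad]:.12f}, not 1")
    return matrix


@dataclasses.dataclass
class ScenarioConfig:
    """One scenario's complete rule set.

    ``modifiers`` are (from_code, to_code, multiplier) triples applied to the
    estimated transition matrix before cost-matrix zeroing.
    """

    name: str
    cost_matrix: np.ndarray  # 6x6 binary, rows=from, cols=to
    neighborhood_weights: dict[int, float]  # code -> weight in [0, 1]
    restricted_classes: frozenset[int] = frozenset()
    modifiers: tuple[tuple[int, int, float], ...] = ()

    def __post_init__(self) -> None:
        self.cost_matrix = np.asarray(self.cost_matrix, dtype=int)
        if self.cost_matrix.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("cost matrix must be 6x6")
        if not set(np.unique(self.cost_matrix)) <= {0, 1}:
            raise ValueError("cost matrix entries must be 0/1")
        if not np.all(np.diag(self.cost_matrix) == 1):
            raise ValueError("cost matrix diagonal must be all ones")
        for code, w in self.neighborhood_weights.items():
            if not 0 <= w <= 1:
                raise ValueError(f"neighborhood weight for class {code} not in [0,1]")
        for f, t, m in self.modifiers:
            if m < 0:
                raise ValueError(f"modifier ({f}->{t}) must be >= 0")
        self.restricted_classes = frozenset(int(c) for c in self.restricted_classes)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cost_matrix": self.cost_matrix.tolist(),
            "neighborhood_weights": {int(k): float(v) for k, v in self.neighborhood_weights.items()},
            "restricted_classes": sorted(self.restricted_classes),
            "modifiers": [[int(f), int(t), float(m)] for f, t, m in self.modifiers],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        return cls(
            name=d["name"],
            cost_matrix=np.asarray(d["cost_matrix"]),
            neighborhood_weights={int(k): float(v) for k, v in d["neighborhood_weights"].items()},
            restricted_classes=frozenset(d.get("restricted_classes", ())),
            modifiers=tuple((int(f), int(t), float(m)) for f, t, m in d.get("modifiers", ())),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def estimate_transition(map_t1: LandUseGrid, map_t2: LandUseGrid) -> np.ndarray:
    """Cross-tabulate a two-epoch pair into a row-stochastic matrix.

    Rows with no cells of the from-class at t1 become identity rows, so the
    matrix is always usable for projection.
    """
    from .grid_io import assert_aligned

    assert_aligned(map_t1, map_t2)
    both = map_t1.mask & map_t2.mask
    if not both.any():
        raise ValueError("no overlapping valid cells between the two epochs")
    a = np.vectorize(_CODE_TO_IDX.get, otypes=[int])(map_t1.values[both])
    b = np.vectorize(_CODE_TO_IDX.get, otypes=[int])(map_t2.values[both])
    counts = np.bincount(a * N_CLASSES + b, minlength=N_CLASSES * N_CLASSES).reshape(
        N_CLASSES, N_CLASSES
    )
    matrix = np.eye(N_CLASSES)
    row_tot = counts.sum(axis=1)
    nz = row_tot > 0
    matrix[nz] = counts[nz] / row_tot[nz, None]
    return matrix


def largest_remainder_round(x: np.ndarray, total: int | None = None) -> np.ndarray:
    """Round non-negative reals to integers conserving their (rounded) sum."""
    x = np.asarray(x, dtype=float)
    if total is None:
        total = int(round(x.sum()))
    floors = np.floor(x).astype(int)
    short = total - int(floors.sum())
    if short < 0:  # only possible via a caller-supplied smaller total
        order = np.argsort(x - floors)  # take from smallest remainders
        for i in order[: -short if short else 0]:
            floors[i] -= 1
        return floors
    remainders = x - floors
    order = np.argsort(-remainders, kind="stable")
    floors[order[:short]] += 1
    return floors


def project_demand(
    counts_t: Sequence[int] | np.ndarray, matrix: np.ndarray, n_steps: int
) -> np.ndarray:
    """Per-class integer cell demand after ``n_steps`` matrix steps.

    ``demand = counts_t @ matrix**n_steps`` rounded by largest remainder so
    the total cell count is conserved exactly.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    matrix = validate_transition_matrix(matrix)
    counts = np.asarray(counts_t, dtype=float)
    if counts.shape != (N_CLASSES,) or (counts < 0).any():
        raise ValueError("counts_t must be 6 non-negative class counts")
    raw = counts @ np.linalg.matrix_power(matrix, n_steps)
    return largest_remainder_round(raw, total=int(round(counts.sum())))


def apply_scenario(matrix: np.ndarray, scenario: ScenarioConfig) -> np.ndarray:
    """Modify a transition matrix by a scenario's rules.

    Each targeted entry is multiplied by its modifier (a multiplier of 0
    forbids the transition), entries forbidden by the cost matrix are zeroed,
    and each row is re-balanced by assigning the deficit or surplus to the
    diagonal (self-persistence), clipped to [0, 1] and renormalized. The
    multiplier therefore keeps its literal meaning for the targeted entry.
    """
    m = validate_transition_matrix(matrix).copy()
    for f, t, mult in scenario.modifiers:
        m[_CODE_TO_IDX[f], _CODE_TO_IDX[t]] *= mult
    m[scenario.cost_matrix == 0] = 0.0
    for i in range(N_CLASSES):
        off = m[i].sum() - m[i, i]
        m[i, i] = 1.0 - off
        if m[i, i] < 0:
            m[i, i] = 0.0
        m[i] = np.clip(m[i], 0.0, 1.0)
        s = m[i].sum()
        if s <= 0:
            raise ValueError(f"scenario {scenario.name!r} forbids every transition from row {i}")
        m[i] /= s
    return validate_transition_matrix(m)


def _cost(rows: str) -> np.ndarray:
    """Parse six row-strings of 0/1 flags (legend order A,F,G,W,C,U)."""
    out = np.array([[int(ch) for ch in row] for row in rows.split()], dtype=int)
    assert out.shape == (N_CLASSES, N_CLASSES)
    return out


def builtin_scenarios() -> dict[str, ScenarioConfig]:
    """The three shipped scenario rule sets, verbatim as published data.

    S1 natural development, S2 ecological protection, S3 sustainable
    development. Note the S1 construction row permits conversions even
    though the accompanying narrative says construction land cannot convert;
    the matrices are kept as printed data and are fully configurable.
    """
    A, F, G, W, C, U = (CLASS_LETTERS[k] for k in "AFGWCU")
    weights = {
        "S1": (0.0, 1.0, 0.59, 0.72, 0.80, 0.62),
        "S2": (0.0, 1.0, 0.56, 0.80, 0.79, 0.63),
        "S3": (0.0, 1.0, 0.63, 0.76, 0.92, 0.66),
    }
    cost = {
        "S1": _cost("111111 011111 011111 000100 011110 111111"),
        "S2": _cost("111100 010100 111010 010100 111110 111111"),
        "S3": _cost("100010 110011 111111 110111 000010 100011"),
    }
    restricted = {"S1": {W}, "S2": {F, W}, "S3": {W}}
    modifiers = {
        "S1": (),
        "S2": (),
        # forest->construction reduced 40%; construction->water increased
        # 120%; water->construction and water->cropland forbidden
        "S3": ((F, C, 0.6), (C, W, 2.2), (W, C, 0.0), (W, A, 0.0)),
    }
    out = {}
    for name in ("S1", "S2", "S3"):
        out[name] = ScenarioConfig(
            name=name,
            cost_matrix=cost[name],
            neighborhood_weights=dict(zip(CLASS_ORDER, weights[name])),
            restricted_classes=frozenset(restricted[name]),
            modifiers=modifiers[name],
        )
    return out
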