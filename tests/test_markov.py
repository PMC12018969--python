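"""Transition estimation, demand projection and scenario algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoscape.grid_io import CLASS_LETTERS, CLASS_ORDER
from ecoscape.markov import (
    ScenarioConfig,
    apply_scenario,
    builtin_scenarios,
    estimate_transition,
    largest_remainder_round,
    project_demand,
    validate_transition_matrix,
)

from conftest import make_landuse

A, F, G, W, C, U = (CLASS_LETTERS[k] for k in "AFGWCU")
IDX = {c: i for i, c in enumerate(CLASS_ORDER)}


def random_stochastic(rng, zero_rows=()):
    m = rng.random((6, 6)) + 0.01
    m /= m.sum(axis=1, keepdims=True)
    return m


# ---------------------------------------------------------------------------
# estimate_transition
# ---------------------------------------------------------------------------


def test_identical_maps_give_identity():
    lu = make_landuse([[1, 2, 3], [4, 5, 6]])
    np.testing.assert_array_equal(estimate_transition(lu, lu), np.eye(6))


def test_two_class_toy_crosstab():
    # 10 cells A->A, 10 cells A->F, 20 cells F->F
    t1 = make_landuse(np.array([1] * 20 + [2] * 20).reshape(4, 10))
    t2_vals = np.array([1] * 10 + [2] * 10 + [2] * 20).reshape(4, 10)
    T = estimate_transition(t1, make_landuse(t2_vals))
    assert T[IDX[A], IDX[A]] == pytest.approx(0.5)
    assert T[IDX[A], IDX[F]] == pytest.approx(0.5)
    assert T[IDX[F], IDX[F]] == pytest.approx(1.0)
    # classes absent at t1 become identity rows
    for code in (G, W, C, U):
        assert T[IDX[code], IDX[code]] == 1.0


def test_no_overlap_raises():
    t1 = make_landuse([[1, 0], [0, 1]])
    t2 = make_landuse([[0, 1], [1, 0]])
    with pytest.raises(ValueError, match="overlap"):
        estimate_transition(t1, t2)


def test_estimate_scale_invariant_under_duplication(rng):
    vals1 = rng.integers(1, 7, size=(10, 10))
    vals2 = rng.integers(1, 7, size=(10, 10))
    T1 = estimate_transition(make_landuse(vals1), make_landuse(vals2))
    T2 = estimate_transition(
        make_landuse(np.tile(vals1, (2, 2))), make_landuse(np.tile(vals2, (2, 2)))
    )
    np.testing.assert_allclose(T1, T2)


# ---------------------------------------------------------------------------
# project_demand
# ---------------------------------------------------------------------------


def test_identity_matrix_preserves_counts():
    counts = np.array([10, 20, 30, 5, 35, 0])
    np.testing.assert_array_equal(project_demand(counts, np.eye(6), 7), counts)


def test_two_class_power_computation():
    # rows (0.9, 0.1) / (0, 1): class-1 demand after 3 steps = 100 * 0.9^3
    m = np.eye(6)
    m[0, 0], m[0, 1] = 0.9, 0.1
    counts = np.array([100, 100, 0, 0, 0, 0])
    demand = project_demand(counts, m, 3)
    assert demand[0] == 73  # round(72.9)
    assert demand[1] == 127
    assert demand.sum() == 200


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(1, 6))
def test_total_conservation_for_random_matrices(seed, steps):
    rng = np.random.default_rng(seed)
    m = random_stochastic(rng)
    counts = rng.integers(0, 5000, size=6)
    demand = project_demand(counts, m, steps)
    assert demand.sum() == counts.sum()
    assert (demand >= 0).all()


def test_convergence_to_stationary_distribution(rng):
    m = random_stochastic(rng)  # strictly positive => ergodic
    counts = np.array([6000, 1000, 1000, 1000, 500, 500])
    demand = project_demand(counts, m, 200)
    eigval, eigvec = np.linalg.eig(m.T)
    stat = np.real(eigvec[:, np.argmax(np.real(eigval))])
    stat = stat / stat.sum() * counts.sum()
    np.testing.assert_allclose(demand, stat, atol=1e-6 * counts.sum() + 1)


def test_nonstochastic_matrix_rejected():
    bad = np.eye(6) * 0.5
    with pytest.raises(ValueError, match="sums"):
        project_demand(np.ones(6, dtype=int) * 10, bad, 1)


def test_largest_remainder_conserves_total():
    x = np.array([1.4, 1.4, 1.2])
    out = largest_remainder_round(x, total=4)
    assert out.sum() == 4 and out.tolist() == [2, 1, 1]


# ---------------------------------------------------------------------------
# apply_scenario & builtin_scenarios
# ---------------------------------------------------------------------------


def test_s1_only_applies_cost_zeroing(rng):
    s1 = builtin_scenarios()["S1"]
    m = random_stochastic(rng)
    out = apply_scenario(m, s1)
    allowed = s1.cost_matrix == 1
    off_diag = ~np.eye(6, dtype=bool)
    np.testing.assert_allclose(out[allowed & off_diag], m[allowed & off_diag])
    assert np.all(out[~allowed] == 0)


def test_s3_forest_to_construction_reduced_40pct():
    m = np.eye(6) * 0.9
    m[IDX[F], IDX[C]] = 0.10
    m[np.arange(6), np.arange(6)] = 1 - m.sum(axis=1) + np.diag(m)
    s3 = builtin_scenarios()["S3"]
    out = apply_scenario(m, s3)
    assert out[IDX[F], IDX[C]] == pytest.approx(0.06)
    # the 0.04 surplus goes back to forest persistence
    assert out[IDX[F], IDX[F]] == pytest.approx(0.94)


def test_s3_construction_to_water_multiplier_is_2_2():
    s3 = builtin_scenarios()["S3"]
    assert (C, W, 2.2) in s3.modifiers
    # the arithmetic, checked with a permissive cost matrix
    permissive = ScenarioConfig(
        name="S3-open", cost_matrix=np.ones((6, 6), dtype=int),
        neighborhood_weights=s3.neighborhood_weights, modifiers=s3.modifiers,
    )
    m = np.eye(6) * 0.99
    m[IDX[C], IDX[W]] = 0.01
    m[np.arange(6), np.arange(6)] = 1 - m.sum(axis=1) + np.diag(m)
    out = apply_scenario(m, permissive)
    assert out[IDX[C], IDX[W]] == pytest.approx(0.022)


def test_water_conversions_forbidden_under_s3():
    s3 = builtin_scenarios()["S3"]
    mods = {(f, t): mult for f, t, mult in s3.modifiers}
    assert mods[(W, C)] == 0.0 and mods[(W, A)] == 0.0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.sampled_from(["S1", "S2", "S3"]))
def test_apply_scenario_preserves_row_stochasticity(seed, name):
    rng = np.random.default_rng(seed)
    out = apply_scenario(random_stochastic(rng), builtin_scenarios()[name])
    validate_transition_matrix(out)


def test_builtin_scenario_tables_verbatim():
    scen = builtin_scenarios()
    assert scen["S2"].restricted_classes == {F, W}
    assert scen["S1"].restricted_classes == {W}
    assert [scen["S1"].neighborhood_weights[c] for c in CLASS_ORDER] == [
        0, 1, 0.59, 0.72, 0.8, 0.62
    ]
    # S1 water row allows only W->W
    w_row = scen["S1"].cost_matrix[IDX[W]]
    assert w_row.tolist() == [0, 0, 0, 1, 0, 0]
    assert scen["S2"].cost_matrix[IDX[A]].tolist() == [1, 1, 1, 1, 0, 0]
    assert scen["S3"].cost_matrix[IDX[C]].tolist() == [0, 0, 0, 0, 1, 0]


def test_scenario_config_yaml_roundtrip(tmp_path):
    sc = builtin_scenarios()["S3"]
    sc.save(tmp_path / "s3.yaml")
    back = ScenarioConfig.load(tmp_path / "s3.yaml")
    assert back.name == sc.name
    np.testing.assert_array_equal(back.cost_matrix, sc.cost_matrix)
    assert back.restricted_classes == sc.restricted_classes
    assert back.modifiers == sc.modifiers


def test_parameter_recovery_on_synthetic_pair(small_spec, small_drivers, small_landuse):
    from ecoscape.synthetic import evolve_landuse

    e2 = evolve_landuse(small_landuse, small_spec, small_drivers)
    T = estimate_transition(small_landuse, e2)
    counts = small_landuse.class_counts()
    for i, code in enumerate(CLASS_ORDER):
        if counts[code] >= 500:
            assert np.abs(T[i] - small_spec.epoch_transition[i]).max() <= 0.03
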