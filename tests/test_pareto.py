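"""Dominance, front maintenance, and hypervolume correctness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qpmhi.pareto import (
    MinMaxSpec,
    ParetoState,
    dominates,
    hvi,
    hvi_batch,
    hypervolume,
    pareto_front,
    relative_hvi,
)

from conftest import brute_force_front, brute_force_hvi, grid_mc_hypervolume


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ((2, 2), (1, 2), True),
        ((1, 2), (1, 2), False),  # no strict improvement
        ((3, 0), (0, 3), False),  # incomparable
        ((1, 2, 3), (1, 2, 2), True),
        ((0, 0), (1, 1), False),
    ],
)
def test_dominates(a, b, expected):
    assert dominates(a, b) is expected


def test_dominates_dimension_mismatch():
    with pytest.raises(ValueError, match="dimension"):
        dominates((1, 2), (1, 2, 3))


def test_pareto_front_examples():
    f = pareto_front([[1, 2], [2, 1], [0.5, 0.5]])
    assert sorted(map(tuple, f)) == [(1, 2), (2, 1)]
    f = pareto_front([[1, 1], [1, 1]])
    assert f.shape == (1, 2)
    assert pareto_front(np.empty((0, 2))).shape[0] == 0


def test_pareto_front_matches_brute_force(rng):
    for _ in range(5):
        pts = rng.normal(size=(50, 2))
        ours = np.array(sorted(map(tuple, pareto_front(pts))))
        np.testing.assert_allclose(ours, brute_force_front(pts))


def test_pareto_front_idempotent_and_order_invariant(rng):
    pts = rng.normal(size=(40, 3))
    f1 = pareto_front(pts)
    assert np.array_equal(
        np.array(sorted(map(tuple, f1))), np.array(sorted(map(tuple, pareto_front(f1))))
    )
    perm = rng.permutation(len(pts))
    f2 = pareto_front(pts[perm])
    np.testing.assert_allclose(
        np.array(sorted(map(tuple, f1))), np.array(sorted(map(tuple, f2)))
    )


def test_hypervolume_closed_form_cases():
    assert hypervolume([[2, 3]], [0, 0]) == pytest.approx(6.0)
    # two rectangles, inclusion-exclusion: 2 + 2 - 1
    assert hypervolume([[1, 2], [2, 1]], [0, 0]) == pytest.approx(3.0)
    # three-box 2-D case by hand: boxes 3x1, 2x2, 1x3 overlapping
    assert hypervolume([[3, 1], [2, 2], [1, 3]], [0, 0]) == pytest.approx(6.0)
    # 3-D: two boxes 2x2x1 and 1x1x2, overlap 1x1x1
    assert hypervolume([[2, 2, 1], [1, 1, 2]], [0, 0, 0]) == pytest.approx(4 + 2 - 1)


def test_hypervolume_rejects_nonfinite_reference():
    with pytest.raises(ValueError, match="finite"):
        hypervolume([[1, 1]], [np.nan, 0])


def test_hypervolume_clips_points_below_reference():
    with pytest.warns(UserWarning, match="clipped"):
        v = hypervolume([[2, 2], [-1, 5]], [0, 0])
    assert v == pytest.approx(4.0)


@pytest.mark.parametrize("m", [2, 3])
def test_hypervolume_matches_grid_mc(m, rng):
    for trial in range(3):
        pts = rng.random(size=(20, m)) * 2
        r = np.zeros(m)
        exact = hypervolume(pts, r)
        front = pareto_front(pts)
        est, se = grid_mc_hypervolume(front, r, n_samples=200_000, seed=trial)
        assert abs(exact - est) < 3 * se + 1e-12


def test_hvi_examples(two_point_state):
    assert hvi([0.5, 0.5], two_point_state) == pytest.approx(0.0)
    assert hvi([2, 2], two_point_state) == pytest.approx(1.0)
    assert hvi([3, 0.5], two_point_state) == pytest.approx(0.5)


def test_hvi_matches_full_recomputation(rng):
    for m in (2, 3):
        pts = rng.random(size=(15, m))
        state = ParetoState.from_observations(pts)
        cands = rng.random(size=(30, m)) * 1.4 - 0.2
        fast = hvi_batch(cands, state)
        slow = np.array([brute_force_hvi(c, state) for c in cands])
        np.testing.assert_allclose(fast, slow, atol=1e-12)


def test_hvi_zero_iff_dominated(rng):
    pts = rng.random(size=(12, 2))
    state = ParetoState.from_observations(pts)
    cands = rng.random(size=(50, 2))
    for c in cands:
        if np.all(c >= state.ref_point):
            dominated = any(
                (np.all(f >= c) and np.any(f > c)) or np.array_equal(f, c)
                for f in state.front
            )
            assert (hvi(c, state) == 0.0) == dominated


def test_hv_monotone_under_addition(rng):
    pts = rng.normal(size=(10, 2))
    state = ParetoState.from_observations(pts)
    hv_prev = state.hv_cached
    for c in rng.normal(size=(20, 2)):
        state.add_points(c[None, :])
        assert state.hv_cached >= hv_prev - 1e-12
        hv_prev = state.hv_cached


def test_adding_dominated_point_leaves_hv_unchanged(two_point_state):
    hv0 = two_point_state.hv_cached
    two_point_state.add_points([[0.5, 0.5]])
    assert two_point_state.hv_cached == pytest.approx(hv0)
    assert len(two_point_state.front) == 2


def test_relative_hvi():
    s0 = ParetoState(front=[[3.0, 1.0]], ref_point=[0.0, 0.0])
    st = ParetoState(front=[[3.0, 1.1]], ref_point=[0.0, 0.0])
    assert relative_hvi(st, s0) == pytest.approx(0.1)
    assert relative_hvi(s0, s0) == 0.0
    degenerate = ParetoState(front=[[0.0, 0.0]], ref_point=[0.0, 0.0])
    with pytest.raises(ValueError, match="undefined"):
        relative_hvi(s0, degenerate)


def test_relative_hvi_monotone_series(rng):
    base = rng.random(size=(5, 2))
    s0 = ParetoState.from_observations(base)
    st = s0.copy()
    prev = 0.0
    for c in rng.random(size=(25, 2)) * 1.5:
        st.add_points(c[None, :])
        cur = relative_hvi(st, s0)
        assert cur >= prev - 1e-12
        prev = cur


def test_minmax_spec_roundtrip():
    spec = MinMaxSpec(("maximize", "minimize"))
    vals = np.array([[1.0, 2.0], [3.0, -4.0]])
    np.testing.assert_allclose(spec.apply(vals), [[1, -2], [3, 4]])
    np.testing.assert_allclose(spec.restore(spec.apply(vals)), vals)
    with pytest.raises(ValueError):
        MinMaxSpec(("up",))


@settings(max_examples=30, deadline=None)
@given(st.lists(st.tuples(st.floats(-5, 5), st.floats(-5, 5)), min_size=1, max_size=15))
def test_front_members_never_dominate_each_other(points):
    front = pareto_front(np.array(points))
    for i in range(len(front)):
        for j in range(len(front)):
            if i != j:
                assert not dominates(front[i], front[j])
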