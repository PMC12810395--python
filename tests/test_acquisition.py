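"""qPMHI estimator, batch selection, fallback, constraints, qPO reduction."""

import itertools

import numpy as np
import pytest
from scipy.stats import norm

from qpmhi.acquisition import (
    AcquisitionResult,
    Constraint,
    ConstraintSpec,
    estimate_pareto_membership,
    estimate_pmhi,
    estimate_pmhi_constrained,
    qpo_single_objective,
    select_batch,
)
from qpmhi.pareto import ParetoState, hypervolume

from conftest import make_draws


def brute_force_pmhi(draws, state):
    """Oracle: recompute HV from scratch per draw per candidate."""
    L, N, _ = draws.samples.shape
    base = hypervolume(state.front, state.ref_point)
    counts = np.zeros(N)
    for l in range(L):
        delta = np.empty(N)
        for i in range(N):
            p = np.maximum(draws.samples[l, i], state.ref_point)
            delta[i] = hypervolume(np.vstack([state.front, p[None, :]]), state.ref_point) - base
        if delta.max() > 0:
            counts[np.argmax(delta)] += 1
    return counts / L


def test_deterministic_draws_give_unit_probability(two_point_state):
    # candidate A improves by 1.0, candidate B by ~0.5, zero variance
    draws = make_draws([[[2.0, 2.0], [3.0, 0.5]]])  # L=1, N=2
    res = estimate_pmhi(draws, two_point_state)
    np.testing.assert_allclose(res.p_max_hvi, [1.0, 0.0])
    assert res.n_nonzero == 1


def test_exchangeable_candidates_split_evenly(two_point_state, rng):
    L = 10_000
    # two candidates with exchangeable iid posteriors straddling the front
    vals = 2.0 + 0.5 * rng.standard_normal((L, 2, 2))
    res = estimate_pmhi(make_draws(vals), two_point_state)
    tol = 3 * np.sqrt(0.25 / L)
    assert abs(res.p_max_hvi[0] - 0.5) < tol
    assert abs(res.p_max_hvi[1] - 0.5) < tol


def test_probabilities_sum_to_one_when_every_draw_improves(two_point_state, rng):
    vals = 2.1 + np.abs(rng.standard_normal((256, 20, 2)))  # always beyond front
    res = estimate_pmhi(make_draws(vals), two_point_state)
    assert res.p_max_hvi.sum() == 1.0  # machine-exact indicator tally


def test_probability_sum_below_one_with_nonimproving_draws(two_point_state, rng):
    vals = rng.standard_normal((200, 5, 2)) * 0.3  # mostly inside the front
    res = estimate_pmhi(make_draws(vals), two_point_state)
    assert 0.0 <= res.p_max_hvi.sum() <= 1.0
    assert res.p_max_hvi.sum() < 1.0


def test_pmhi_matches_brute_force_oracle(rng):
    state = ParetoState.from_observations(rng.random((6, 2)))
    vals = rng.standard_normal((40, 7, 2)) * 0.8 + 0.7
    draws = make_draws(vals)
    fast = estimate_pmhi(draws, state).p_max_hvi
    slow = brute_force_pmhi(draws, state)
    np.testing.assert_array_equal(fast, slow)


def test_pmhi_invariances(rng, two_point_state):
    vals = rng.standard_normal((64, 9, 2)) + 1.5
    p = estimate_pmhi(make_draws(vals), two_point_state).p_max_hvi
    # candidate permutation equivariance
    perm = rng.permutation(9)
    p_perm = estimate_pmhi(make_draws(vals[:, perm, :]), two_point_state).p_max_hvi
    np.testing.assert_array_equal(p_perm, p[perm])
    # objective relabeling invariance (front and ref are symmetric here)
    state_swapped = ParetoState(
        front=two_point_state.front[:, ::-1], ref_point=two_point_state.ref_point[::-1]
    )
    p_swap = estimate_pmhi(make_draws(vals[:, :, ::-1]), state_swapped).p_max_hvi
    np.testing.assert_array_equal(p_swap, p)


def test_select_batch_sorts_by_probability():
    res = AcquisitionResult(p_max_hvi=np.array([0.5, 0.3, 0.2]))
    np.testing.assert_array_equal(select_batch(res, 2), [0, 1])


def test_select_batch_validates_q():
    res = AcquisitionResult(p_max_hvi=np.array([0.5, 0.5]))
    with pytest.raises(ValueError, match="positive"):
        select_batch(res, 0)
    with pytest.raises(ValueError, match="exceeds"):
        select_batch(res, 3)


def test_select_batch_fallback_uses_pareto_membership():
    res = AcquisitionResult(
        p_max_hvi=np.array([0.6, 0.3, 0.1, 0.0, 0.0, 0.0]),
        p_pareto_member=np.array([0.0, 0.1, 0.2, 0.9, 0.3, 0.8]),
    )
    sel = select_batch(res, 5)
    np.testing.assert_array_equal(sel[:3], [0, 1, 2])  # by p-hat
    np.testing.assert_array_equal(sorted(sel[3:]), [3, 5])  # by membership


def test_select_batch_equals_exhaustive_subset_maximization(rng):
    for _ in range(25):
        n = int(rng.integers(4, 13))
        q = int(rng.integers(1, min(n, 6)))
        p = rng.random(n)
        p /= p.sum()
        res = AcquisitionResult(p_max_hvi=p, p_pareto_member=rng.random(n))
        sel = set(select_batch(res, q).tolist())
        best = max(itertools.combinations(range(n), q), key=lambda s: p[list(s)].sum())
        assert p[list(sel)].sum() == pytest.approx(p[list(best)].sum())


def test_pareto_membership_extremes(two_point_state):
    always_dominating = np.full((50, 1, 2), 5.0)
    always_inside = np.full((50, 1, 2), 0.2)
    assert estimate_pareto_membership(make_draws(always_dominating), two_point_state)[0] == 1.0
    assert estimate_pareto_membership(make_draws(always_inside), two_point_state)[0] == 0.0


def test_pareto_membership_matches_orthant_integral(rng):
    """Nondomination probability vs closed-form Gaussian orthant mass."""
    state = ParetoState(front=[[1.0, 1.5]], ref_point=[0.0, 0.0])
    L = 10_000
    mu = np.array([[0.6, 0.9], [1.4, 0.2]])
    sd = np.array([[0.5, 0.7], [0.3, 0.6]])
    vals = mu[None, :, :] + sd[None, :, :] * rng.standard_normal((L, 2, 2))
    est = estimate_pareto_membership(make_draws(vals), state)
    for i in range(2):
        p_dom = norm.cdf((1.0 - mu[i, 0]) / sd[i, 0]) * norm.cdf((1.5 - mu[i, 1]) / sd[i, 1])
        exact = 1.0 - p_dom
        se = np.sqrt(exact * (1 - exact) / L)
        assert abs(est[i] - exact) < 3 * se + 1e-9


def test_constrained_inactive_constraint_is_identity(two_point_state, rng):
    vals = rng.standard_normal((64, 6, 2)) + 1.8
    draws = make_draws(vals)
    aux = make_draws(np.zeros((64, 6, 1)))
    spec = ConstraintSpec((Constraint(index=0, direction="le", threshold=10.0),))
    res_c = estimate_pmhi_constrained(draws, aux, two_point_state, spec)
    res_u = estimate_pmhi(draws, two_point_state)
    np.testing.assert_array_equal(res_c.p_max_hvi, res_u.p_max_hvi)


def test_constrained_excluded_candidate_gets_zero(two_point_state, rng):
    vals = rng.standard_normal((32, 3, 2)) + 2.0
    aux = np.zeros((32, 3, 1))
    aux[:, 0, 0] = 99.0  # candidate 0 always infeasible
    spec = ConstraintSpec((Constraint(index=0, direction="le", threshold=1.0),))
    res = estimate_pmhi_constrained(make_draws(vals), make_draws(aux), two_point_state, spec)
    assert res.p_max_hvi[0] == 0.0


def test_constrained_hand_counted_micro_example(two_point_state):
    # 4 draws, 2 candidates; A wins every draw unconstrained, but is
    # infeasible in draws 0 and 2 -> B wins those; p = (0.5, 0.5)
    vals = np.array(
        [[[3.0, 3.0], [2.5, 2.5]]] * 4
    )
    aux = np.zeros((4, 2, 1))
    aux[0, 0, 0] = aux[2, 0, 0] = 5.0
    spec = ConstraintSpec((Constraint(index=0, direction="le", threshold=1.0),))
    res = estimate_pmhi_constrained(
        make_draws(vals), make_draws(aux), two_point_state, spec
    )
    np.testing.assert_allclose(res.p_max_hvi, [0.5, 0.5])


def test_constrained_all_infeasible_draws_renormalize(two_point_state):
    # candidate improves in all 4 draws but the whole pool is infeasible in
    # two of them; those draws drop from the denominator
    vals = np.array([[[3.0, 3.0], [0.1, 0.1]]] * 4)
    aux = np.zeros((4, 2, 1))
    aux[1, :, 0] = aux[3, :, 0] = 5.0  # every candidate infeasible
    spec = ConstraintSpec((Constraint(index=0, direction="le", threshold=1.0),))
    res = estimate_pmhi_constrained(
        make_draws(vals), make_draws(aux), two_point_state, spec
    )
    np.testing.assert_allclose(res.p_max_hvi, [1.0, 0.0])


def test_constrained_rejects_misaligned_shapes(two_point_state, rng):
    draws = make_draws(rng.standard_normal((8, 4, 2)))
    aux = make_draws(rng.standard_normal((8, 5, 1)))
    spec = ConstraintSpec((Constraint(index=0, direction="le", threshold=0.0),))
    with pytest.raises(ValueError, match="misaligned"):
        estimate_pmhi_constrained(draws, aux, two_point_state, spec)


def test_qpo_deterministic_ordering():
    draws = make_draws(np.array([[[1.0], [3.0], [2.0]]] * 5))
    res = qpo_single_objective(draws)
    np.testing.assert_allclose(res.p_max_hvi, [0.0, 1.0, 0.0])


def test_qpo_symmetric_candidates(rng):
    L = 10_000
    draws = make_draws(rng.standard_normal((L, 2, 1)))
    res = qpo_single_objective(draws)
    assert abs(res.p_max_hvi[0] - 0.5) < 3 * np.sqrt(0.25 / L)


def test_qpo_reduces_to_pmhi_at_m_equals_one(rng):
    incumbent = 0.4
    vals = rng.standard_normal((128, 6, 1))
    draws = make_draws(vals)
    res_qpo = qpo_single_objective(draws, incumbent_best=incumbent)
    state = ParetoState(front=[[incumbent]], ref_point=[incumbent])
    res_pmhi = estimate_pmhi(draws, state)
    np.testing.assert_array_equal(res_qpo.p_max_hvi, res_pmhi.p_max_hvi)


def test_qpo_rejects_multiobjective_draws(rng):
    with pytest.raises(ValueError, match="M = 1"):
        qpo_single_objective(make_draws(rng.standard_normal((4, 3, 2))))
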