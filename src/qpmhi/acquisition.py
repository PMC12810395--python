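"""qPMHI: batch acquisition by probability of maximum hypervolume improvement.

For each joint posterior draw ``l`` over the candidate pool we compute the
hypervolume improvement ``ΔHV^(l)(x)`` of every candidate against the FIXED
incumbent front, find the unique per-draw maximizer, and tally indicators:

    p̂(x) = (1/L) Σ_l 1{x = argmax_x' ΔHV^(l)(x')}

Because the argmax events are mutually exclusive, the batch acquisition
α(X_cand) = Σ_{x in X_cand} p̂(x) is additive, so picking the q candidates
with the largest p̂ is *exactly* optimal over all size-q subsets.  When
fewer than q candidates have p̂ > 0, the remaining slots are filled by the
highest probability of lying on the (observed) Pareto front.

Tie handling: draws where no candidate strictly improves the front credit
no one (so Σ p̂ may be < 1); exact floating-point ties in the argmax go to
the lowest pool index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pareto import ParetoState, hvi_batch
from .surrogate import PosteriorDraws

__all__ = [
    "AcquisitionResult",
    "ConstraintSpec",
    "estimate_pmhi",
    "estimate_pareto_membership",
    "estimate_pmhi_constrained",
    "select_batch",
    "qpo_single_objective",
]


@dataclass
class AcquisitionResult:
    """Per-candidate qPMHI probabilities plus the selected batch."""

    p_max_hvi: np.ndarray
    p_pareto_member: np.ndarray = None  # type: ignore[assignment]
    selected: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    L_used: int = 0

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.p_max_hvi))


@dataclass(frozen=True)
class Constraint:
    """One black-box constraint on an auxiliary (or objective) output."""

    index: int
    direction: str  # 'ge' or 'le'
    threshold: float

    def feasible(self, values: np.ndarray) -> np.ndarray:
        if not np.isfinite(self.threshold):
            raise ValueError("constraint threshold must be finite")
        if self.direction == "ge":
            return values >= self.threshold
        if self.direction == "le":
            return values <= self.threshold
        raise ValueError(f"unknown constraint direction {self.direction!r}")


@dataclass(frozen=True)
class ConstraintSpec:
    constraints: tuple[Constraint, ...]

    def feasibility(self, aux: np.ndarray) -> np.ndarray:
        """(L, N) feasibility mask from (L, N, K) auxiliary draws."""
        mask = np.ones(aux.shape[:2], dtype=bool)
        for c in self.constraints:
            mask &= c.feasible(aux[:, :, c.index])
        return mask


def _delta_hv(draws: PosteriorDraws, state: ParetoState) -> np.ndarray:
    """(L, N) hypervolume improvements against the fixed incumbent front."""
    L, N, M = draws.samples.shape
    if M != state.m:
        raise ValueError("draws/state objective dimension mismatch")
    out = np.empty((L, N))
    for l in range(L):
        out[l] = hvi_batch(draws.samples[l], state)
    return out


def _tally(delta: np.ndarray, feasible: np.ndarray | None = None):
    """Per-draw argmax indicator counts.

    Returns (counts, n_contributing_draws).  Within each draw, infeasible
    candidates are excluded; a draw whose feasible maximum improvement is
    exactly zero credits no candidate.  Ties go to the lowest index
    (np.argmax convention).
    """
    L, N = delta.shape
    d = delta.copy()
    if feasible is not None:
        d[~feasible] = -np.inf
        contributing = feasible.any(axis=1)
    else:
        contributing = np.ones(L, dtype=bool)
    counts = np.zeros(N)
    winners = np.argmax(d, axis=1)
    best = d[np.arange(L), winners]
    credit = contributing & (best > 0)
    np.add.at(counts, winners[credit], 1.0)
    return counts, int(contributing.sum())


def estimate_pmhi(draws: PosteriorDraws, state: ParetoState) -> AcquisitionResult:
    """Monte-Carlo estimate of each candidate's maximal-HVI probability."""
    delta = _delta_hv(draws, state)
    counts, _ = _tally(delta)
    p = counts / draws.L
    p_member = estimate_pareto_membership(draws, state)
    return AcquisitionResult(p_max_hvi=p, p_pareto_member=p_member, L_used=draws.L)


def estimate_pareto_membership(draws: PosteriorDraws, state: ParetoState) -> np.ndarray:
    """P(candidate's sampled objectives are nondominated by the observed front).

    The membership definition is against the current *observed* front (not a
    posterior-sampled pool front): cheap, monotone in candidate optimism,
    and independent of pool composition.
    """
    front = state.front
    L, N, M = draws.samples.shape
    if len(front) == 0:
        return np.ones(N)
    counts = np.zeros(N)
    for l in range(L):
        pts = draws.samples[l]  # (N, M)
        ge = np.all(front[None, :, :] >= pts[:, None, :], axis=2)
        gt = np.any(front[None, :, :] > pts[:, None, :], axis=2)
        dominated = np.any(ge & gt, axis=1)
        counts += ~dominated
    return counts / L


def select_batch(result: AcquisitionResult, q: int) -> np.ndarray:
    """Top-q pool indices by p̂, with Pareto-membership fallback.

    The additive decomposition makes the p̂-sorted prefix exactly optimal
    over all size-q subsets.  Slots beyond ``n_nonzero`` are filled by
    descending Pareto-membership probability among unselected candidates.
    Ties break toward the lower index; updates ``result.selected`` in place
    and returns it.
    """
    if q <= 0:
        raise ValueError("q must be positive")
    p = result.p_max_hvi
    n = len(p)
    if q > n:
        raise ValueError(f"q={q} exceeds pool size {n}")
    order = np.lexsort((np.arange(n), -p))
    k = min(q, result.n_nonzero)
    chosen = list(order[:k])
    if k < q:
        if result.p_pareto_member is None:
            raise ValueError("fallback requires Pareto-membership probabilities")
        taken = set(chosen)
        fb = np.lexsort((np.arange(n), -result.p_pareto_member))
        for i in fb:
            if len(chosen) >= q:
                break
            if i not in taken:
                chosen.append(i)
                taken.add(i)
    result.selected = np.asarray(chosen, dtype=int)
    return result.selected


def estimate_pmhi_constrained(
    draws: PosteriorDraws,
    aux_draws: PosteriorDraws,
    state: ParetoState,
    constraints: ConstraintSpec,
) -> AcquisitionResult:
    """qPMHI with per-sample feasibility screening.

    Within each draw, candidates violating any constraint under that draw's
    auxiliary sample are excluded from the argmax.  Draws in which every
    candidate is infeasible contribute to no one; probabilities are
    normalized over the contributing draws.  If no draw has a feasible
    candidate, all p̂ = 0 and the fallback membership is likewise
    constrained (averaged over per-draw feasible indicators).
    """
    if aux_draws.samples.shape[:2] != draws.samples.shape[:2]:
        raise ValueError("aux draws misaligned with objective draws")
    feasible = constraints.feasibility(aux_draws.samples)
    delta = _delta_hv(draws, state)
    counts, n_contrib = _tally(delta, feasible)
    p = counts / n_contrib if n_contrib > 0 else np.zeros(draws.N)
    # constrained membership: nondominated AND feasible under the draw
    front = state.front
    mem = np.zeros(draws.N)
    for l in range(draws.L):
        pts = draws.samples[l]
        ge = np.all(front[None, :, :] >= pts[:, None, :], axis=2)
        gt = np.any(front[None, :, :] > pts[:, None, :], axis=2)
        nondom = ~np.any(ge & gt, axis=1)
        mem += nondom & feasible[l]
    mem /= draws.L
    return AcquisitionResult(p_max_hvi=p, p_pareto_member=mem, L_used=draws.L)


def qpo_single_objective(
    draws: PosteriorDraws, incumbent_best: float = -np.inf
) -> AcquisitionResult:
    """Single-objective reduction: probability of being the sampled pool maximum.

    p̂(x) is the fraction of draws in which x attains the pool-wide maximum
    sampled value, credited only when that maximum improves on
    ``incumbent_best``; this coincides exactly with :func:`estimate_pmhi`
    run at M = 1 with front = {incumbent_best} and r = incumbent_best.
    """
    if draws.M != 1:
        raise ValueError("qPO requires M = 1 draws")
    vals = draws.samples[:, :, 0]
    L, N = vals.shape
    counts = np.zeros(N)
    winners = np.argmax(vals, axis=1)
    best = vals[np.arange(L), winners]
    credit = best > incumbent_best
    np.add.at(counts, winners[credit], 1.0)
    p = counts / L
    member = (
        (vals > incumbent_best).mean(axis=0)
        if np.isfinite(incumbent_best)
        else np.ones(N)
    )
    return AcquisitionResult(p_max_hvi=p, p_pareto_member=member, L_used=L)
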