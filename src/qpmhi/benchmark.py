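"""Fixed-pool ablation harness for comparing acquisition functions.

The harness isolates the selection stage: a prefixed synthetic pool with
known ground-truth objectives, a shared initial labeled subset per
replicate (paired-seed design), and several acquisitions run under
identical conditions.  Tracked metrics are the hypervolume of the labeled
front and the fraction of the pool's true Pareto-optimal members
recovered, per iteration per replicate, with normal-approximation 95%
confidence bands over replicates.

Acquisitions:

``qpmhi``   probability-of-maximum-HVI ranking (the package's own method)
``greedy``  rank candidates by the HVI of their posterior mean (myopic)
``random``  uniform sampling without replacement (the Sobol-style
            space-filling baseline degenerates to uniform choice on an
            unstructured discrete pool; ``sobol`` is accepted as an alias)
"""

from __future__ import annotations

import string as _string
from dataclasses import dataclass

import numpy as np

from . import surrogate as sg
from .acquisition import estimate_pmhi, select_batch
from .features import hash_features
from .oracles import string_objectives
from .pareto import ParetoState, hvi_batch, pareto_front

__all__ = ["SyntheticPool", "Scenario", "MetricSeries", "make_synthetic_pool", "run_ablation"]


@dataclass(frozen=True)
class SyntheticPool:
    """Molecule-string-keyed pool with known M-objective ground truth."""

    strings: tuple[str, ...]
    features: np.ndarray  # (n, d) hash embedding
    objectives: np.ndarray  # (n, M), maximization orientation
    true_front_idx: np.ndarray  # indices of the pool's Pareto-optimal members

    @property
    def n(self) -> int:
        return len(self.strings)


def make_synthetic_pool(
    n: int, m: int = 2, rho: float = -0.5, seed: int = 0
) -> SyntheticPool:
    """Build a deterministic pool of n unique strings with correlated objectives.

    ``rho`` controls the cross-objective correlation of the ground truth:
    negative values create a trade-off (many mutually nondominated points),
    +1 collapses the front toward a single common maximizer.  The true
    Pareto subset is computed by exhaustive dominance scan and stored.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(_string.ascii_uppercase))
    strings: dict[str, None] = {}
    while len(strings) < n:
        length = int(rng.integers(8, 13))
        s = "".join(rng.choice(alphabet, size=length))
        strings.setdefault(s)
    strings = tuple(strings)
    feats = hash_features(strings, dim=m + 2)
    objs = string_objectives(strings, m=m, rho=rho)
    front = pareto_front(objs)
    front_set = {tuple(p) for p in front}
    idx = np.array([i for i, y in enumerate(objs) if tuple(y) in front_set])
    return SyntheticPool(strings=strings, features=feats, objectives=objs, true_front_idx=idx)


@dataclass(frozen=True)
class Scenario:
    """Fully reproducible ablation configuration."""

    n_pool: int = 2000
    m: int = 2
    rho: float = -0.5
    n_init: int = 100
    q: int = 50
    iterations: int = 10
    L: int = 64
    replicates: int = 5
    seed: int = 0
    acquisitions: tuple[str, ...] = ("qpmhi", "greedy", "random")


@dataclass
class MetricSeries:
    """Per-iteration HV and Pareto-recovery trajectories per acquisition."""

    hv: dict[str, np.ndarray]  # name -> (replicates, iterations + 1)
    recovery: dict[str, np.ndarray]
    scenario: Scenario = None  # type: ignore[assignment]

    def summary(self, which: str = "hv"):
        """Mean trajectory and 95% normal-approximation half-widths."""
        data = getattr(self, which)
        out = {}
        for name, arr in data.items():
            mean = arr.mean(axis=0)
            half = 1.96 * arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 else np.zeros_like(mean)
            out[name] = (mean, half)
        return out


def _select(
    name: str,
    model: sg.SurrogateModel,
    pool_feats: np.ndarray,
    state: ParetoState,
    q: int,
    L: int,
    rng: np.random.Generator,
    seed: int,
) -> np.ndarray:
    n = pool_feats.shape[0]
    q = min(q, n)
    if name in ("random", "sobol"):
        return rng.choice(n, size=q, replace=False)
    if name == "greedy":
        mean = model.predict(pool_feats)
        imp = hvi_batch(mean, state)
        return np.lexsort((np.arange(n), -imp))[:q]
    if name == "qpmhi":
        draws = sg.sample_joint(model, pool_feats, L, seed)
        result = estimate_pmhi(draws, state)
        return select_batch(result, q)
    raise ValueError(f"unknown acquisition {name!r}")


def run_ablation(scenario: Scenario, pool: SyntheticPool | None = None) -> MetricSeries:
    """Seeded fixed-pool replicates of batch BO per acquisition.

    All acquisitions within a replicate share the initial labeled subset
    and the reference point (the nadir of the initial labels), so
    differences in the trajectories are attributable to selection alone.
    """
    if pool is None:
        pool = make_synthetic_pool(scenario.n_pool, scenario.m, scenario.rho, scenario.seed)
    T = scenario.iterations
    R = scenario.replicates
    true_front = set(pool.true_front_idx.tolist())
    hv = {a: np.zeros((R, T + 1)) for a in scenario.acquisitions}
    rec = {a: np.zeros((R, T + 1)) for a in scenario.acquisitions}

    for r in range(R):
        rep_seed = int(np.random.SeedSequence([scenario.seed, r]).generate_state(1)[0] % 2**31)
        init_rng = np.random.default_rng(rep_seed)
        init_idx = init_rng.choice(pool.n, size=scenario.n_init, replace=False)
        ref = pool.objectives[init_idx].min(axis=0)

        for a in scenario.acquisitions:
            labeled = list(init_idx)
            state = ParetoState(front=pool.objectives[labeled], ref_point=ref)
            hv[a][r, 0] = state.hv_cached
            rec[a][r, 0] = len(true_front & set(labeled)) / len(true_front)
            acq_rng = np.random.default_rng(rep_seed + 1)

            for t in range(1, T + 1):
                remaining = np.array(sorted(set(range(pool.n)) - set(labeled)))
                if len(remaining) == 0:
                    hv[a][r, t] = hv[a][r, t - 1]
                    rec[a][r, t] = rec[a][r, t - 1]
                    continue
                model = sg.fit(
                    pool.features[labeled], pool.objectives[labeled], random_state=rep_seed
                )
                sel_local = _select(
                    a,
                    model,
                    pool.features[remaining],
                    state,
                    scenario.q,
                    scenario.L,
                    acq_rng,
                    seed=rep_seed * 1000 + t,
                )
                chosen = remaining[np.asarray(sel_local, dtype=int)]
                labeled.extend(chosen.tolist())
                state.add_points(pool.objectives[chosen])
                hv[a][r, t] = state.hv_cached
                rec[a][r, t] = len(true_front & set(labeled)) / len(true_front)

    return MetricSeries(hv=hv, recovery=rec, scenario=scenario)


def metrics_table(series: MetricSeries):
    """Long-format table (iteration, replicate, acquisition, hv, recovery)."""
    import pandas as pd

    rows = []
    for a in series.hv:
        R, T1 = series.hv[a].shape
        for r in range(R):
            for t in range(T1):
                rows.append(
                    dict(
                        acquisition=a,
                        replicate=r,
                        iteration=t,
                        hv=series.hv[a][r, t],
                        recovery=series.recovery[a][r, t],
                    )
                )
    return pd.DataFrame(rows)
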