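"""Iterative generate-then-optimize batch Bayesian optimization loop.

Each iteration: (1) refit the surrogate on all labeled data, (2) generate
a fresh candidate pool with the surrogate-guided GA, (3) draw L joint
posterior samples over the pool, (4) score candidates with qPMHI and pick
the top-q batch (Pareto-membership fallback when fewer than q candidates
have positive probability), (5) query the oracle on the batch and fold the
new labels into the dataset and Pareto front.  The reference point is
fixed at the start of the run as the componentwise nadir of the initial
labeled objectives (minus an optional slack), so hypervolume trajectories
are comparable across iterations.

Runs are deterministic functions of the master seed: per-iteration
fit/sample/generator streams are split from ``SeedSequence([master, t])``,
which also makes checkpoint resume bit-reproducible.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import surrogate as sg
from .acquisition import estimate_pmhi, select_batch
from .config import RunConfig
from .features import FEATURIZERS
from .generator import FilterSpec, GAConfig, generate_pool
from .io import read_labeled_table, write_labeled_table
from .oracles import Oracle, get_oracle
from .pareto import MinMaxSpec, ParetoState

logger = logging.getLogger(__name__)

__all__ = ["RunHistory", "run", "resume", "score_pool"]

CHECKPOINT_VERSION = 1

_METRIC_COLS = [
    "iteration",
    "n_labeled",
    "hv",
    "relative_hvi",
    "n_nonzero",
    "pool_size",
]


@dataclass
class RunHistory:
    """Complete transcript of a run: labeled data, metrics, stop reason."""

    config: RunConfig
    labeled: pd.DataFrame  # smiles, objectives (raw orientation), iteration
    metrics: pd.DataFrame
    stop_reason: str = "running"
    t_done: int = 0

    @property
    def final_hv(self) -> float:
        return float(self.metrics["hv"].iloc[-1])


def _iteration_seeds(master: int, t: int) -> tuple[int, int, int]:
    """Deterministic (fit, sample, generator) seeds for iteration t."""
    ss = np.random.SeedSequence([int(master), int(t)])
    kids = ss.spawn(3)
    return tuple(int(k.generate_state(1)[0] % 2**31) for k in kids)


def _pareto_state(y_internal: np.ndarray, ref: np.ndarray) -> ParetoState:
    return ParetoState(front=y_internal, ref_point=ref)


def _evaluate_batch(
    oracle: Oracle,
    pool_smiles: list[str],
    ranked: list[int],
    q: int,
) -> tuple[list[int], np.ndarray]:
    """Query the oracle down the ranking, substituting failures.

    A candidate whose oracle call raises is skipped (logged) and replaced
    by the next-ranked candidate, so a clean batch of q labels is returned
    whenever the pool allows it.
    """
    got_idx: list[int] = []
    got_y: list[np.ndarray] = []
    for i in ranked:
        if len(got_idx) >= q:
            break
        try:
            y = oracle.evaluate([pool_smiles[i]])[0]
        except Exception as exc:  # oracle failure: substitute next-ranked
            logger.warning("oracle failed on %s (%s); substituting", pool_smiles[i], exc)
            continue
        got_idx.append(i)
        got_y.append(y)
    return got_idx, np.array(got_y) if got_y else np.empty((0, oracle.m))


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)


def _checkpoint(out_dir: Path, history: RunHistory) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_labeled_table(history.labeled, out_dir / "labeled.csv")
    history.metrics.to_csv(out_dir / "metrics.csv", index=False, float_format="%.17g")
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": history.config.model_dump(),
        "t_done": history.t_done,
        "stop_reason": history.stop_reason,
    }
    _atomic_write(out_dir / "checkpoint.json", json.dumps(meta, indent=1))


def _dump_acquisition(out_dir: Path, t: int, pool_smiles, result) -> None:
    df = pd.DataFrame(
        {
            "pool_id": np.arange(len(pool_smiles)),
            "smiles": pool_smiles,
            "p_max_hvi": result.p_max_hvi,
            "p_pareto_member": result.p_pareto_member,
            "selected": np.isin(np.arange(len(pool_smiles)), result.selected).astype(int),
        }
    )
    df.to_csv(out_dir / f"acquisition_{t:03d}.csv", index=False, float_format="%.17g")


def run(
    cfg: RunConfig,
    init_table: Optional[pd.DataFrame] = None,
    oracle: Optional[Oracle] = None,
    out_dir: Optional[Path | str] = None,
    stop_callback: Optional[Callable[[RunHistory], bool]] = None,
) -> RunHistory:
    """Execute T iterations of the batch BO loop from the initial dataset.

    ``init_table`` holds the seed molecules and their raw objective values
    (columns: smiles + objective names); if omitted it is loaded from
    ``cfg.init_data``.  ``oracle`` defaults to the registry entry named in
    the config.  Early stopping: optional HV-stall patience from the
    config, or a user callback returning True to stop.
    """
    if oracle is None:
        oracle = get_oracle(cfg.oracle)
    if tuple(oracle.directions) != cfg.directions:
        raise ValueError("config objective directions disagree with the oracle")
    if init_table is None:
        if cfg.init_data is None:
            raise ValueError("no initial data: provide init_table or cfg.init_data")
        init_table = read_labeled_table(cfg.init_data, cfg.objective_names)

    labeled = init_table.copy().reset_index(drop=True)
    if "iteration" not in labeled.columns:
        labeled["iteration"] = 0
    minmax = MinMaxSpec(cfg.directions)
    names = cfg.objective_names

    y_int = minmax.apply(labeled[names].to_numpy(dtype=float))
    ref = y_int.min(axis=0) - cfg.eps_ref
    state = _pareto_state(y_int, ref)
    hv0 = state.hv_cached

    metrics = [
        dict(
            iteration=0,
            n_labeled=len(labeled),
            hv=state.hv_cached,
            relative_hvi=0.0,
            n_nonzero=np.nan,
            pool_size=np.nan,
        )
    ]
    history = RunHistory(
        config=cfg,
        labeled=labeled,
        metrics=pd.DataFrame(metrics, columns=_METRIC_COLS),
        t_done=0,
    )
    out_path = Path(out_dir) if out_dir is not None else None
    return _iterate(history, state, hv0, oracle, minmax, out_path, stop_callback)


def _iterate(
    history: RunHistory,
    state: ParetoState,
    hv0: float,
    oracle: Oracle,
    minmax: MinMaxSpec,
    out_dir: Optional[Path],
    stop_callback: Optional[Callable[[RunHistory], bool]] = None,
) -> RunHistory:
    cfg = history.config
    names = cfg.objective_names
    featurizer = FEATURIZERS[cfg.featurizer]
    filters = FilterSpec(
        max_smiles_length=cfg.filters.max_smiles_length,
        max_sa_score=cfg.filters.max_sa_score,
        substructure_required=cfg.filters.substructure_required,
        sa_method=cfg.filters.sa_method,
    )
    metrics = history.metrics.to_dict("records")
    labeled = history.labeled
    stall = 0

    for t in range(history.t_done + 1, cfg.T + 1):
        fit_seed, sample_seed, ga_seed = _iteration_seeds(cfg.seed, t)
        smiles = labeled["smiles"].tolist()
        X = featurizer(smiles)
        Y = minmax.apply(labeled[names].to_numpy(dtype=float))
        model = sg.fit(X, Y, random_state=fit_seed)

        ga_cfg = GAConfig(
            population_size=cfg.ga.population_size,
            generations=cfg.ga.generations,
            mutation_rate=cfg.ga.mutation_rate,
            crossover_rate=cfg.ga.crossover_rate,
            elite_fraction=cfg.ga.elite_fraction,
            beta=cfg.ga.beta,
            pool_target=cfg.N,
            seed=ga_seed,
        )
        pool = generate_pool(smiles, model, ga_cfg, filters, featurizer, exclude=smiles)
        pool_smiles = [c.smiles for c in pool]

        draws = sg.sample_joint(model, featurizer(pool_smiles), cfg.L, sample_seed)
        result = estimate_pmhi(draws, state)
        q = min(cfg.q, len(pool_smiles))
        select_batch(result, q)
        rank_rest = np.lexsort(
            (np.arange(len(pool_smiles)), -result.p_pareto_member, -result.p_max_hvi)
        )
        ranked = list(result.selected) + [i for i in rank_rest if i not in set(result.selected)]
        got_idx, y_raw = _evaluate_batch(oracle, pool_smiles, ranked, q)
        if not got_idx:
            history.stop_reason = "oracle_exhausted"
            break

        new = pd.DataFrame({"smiles": [pool_smiles[i] for i in got_idx]})
        new[names] = y_raw
        new["iteration"] = t
        labeled = pd.concat([labeled, new], ignore_index=True)
        hv_prev = state.hv_cached
        state.add_points(minmax.apply(y_raw))

        metrics.append(
            dict(
                iteration=t,
                n_labeled=len(labeled),
                hv=state.hv_cached,
                relative_hvi=(state.hv_cached - hv0) / hv0 if hv0 > 0 else np.nan,
                n_nonzero=result.n_nonzero,
                pool_size=len(pool_smiles),
            )
        )
        history.labeled = labeled
        history.metrics = pd.DataFrame(metrics, columns=_METRIC_COLS)
        history.t_done = t

        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
            _dump_acquisition(out_dir, t, pool_smiles, result)
            _checkpoint(out_dir, history)

        stall = stall + 1 if state.hv_cached <= hv_prev else 0
        if cfg.patience is not None and stall >= cfg.patience:
            history.stop_reason = "hv_stall"
            break
        if stop_callback is not None and stop_callback(history):
            history.stop_reason = "callback"
            break
    else:
        history.stop_reason = "budget_exhausted" if cfg.T > 0 else "no_iterations"

    if out_dir is not None:
        _checkpoint(out_dir, history)
    return history


def resume(out_dir: Path | str) -> RunHistory:
    """Continue an interrupted run from its checkpoint directory.

    The per-iteration seed derivation depends only on (master seed, t), so
    the continued run is bit-identical to an uninterrupted one.  Resuming
    a finished run is a no-op returning the final state; a corrupted or
    version-mismatched checkpoint raises without partial mutation.
    """
    out_dir = Path(out_dir)
    meta_path = out_dir / "checkpoint.json"
    try:
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"corrupted or missing checkpoint at {meta_path}: {exc}") from None
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(
            f"checkpoint version {meta.get('version')} incompatible with {CHECKPOINT_VERSION}"
        )
    cfg = RunConfig.model_validate(meta["config"])
    labeled = read_labeled_table(out_dir / "labeled.csv", cfg.objective_names)
    metrics = pd.read_csv(out_dir / "metrics.csv")
    history = RunHistory(
        config=cfg,
        labeled=labeled,
        metrics=metrics,
        stop_reason=meta["stop_reason"],
        t_done=int(meta["t_done"]),
    )
    if history.t_done >= cfg.T or history.stop_reason in (
        "hv_stall",
        "callback",
        "oracle_exhausted",
        "no_iterations",
    ):
        return history  # finished run: resume is a no-op

    minmax = MinMaxSpec(cfg.directions)
    names = cfg.objective_names
    y_int = minmax.apply(labeled[names].to_numpy(dtype=float))
    init_mask = labeled["iteration"] == 0
    ref = y_int[init_mask.to_numpy()].min(axis=0) - cfg.eps_ref
    state = _pareto_state(y_int, ref)
    hv0 = _pareto_state(y_int[init_mask.to_numpy()], ref).hv_cached
    oracle = get_oracle(cfg.oracle)
    return _iterate(history, state, hv0, oracle, minmax, out_dir)


def score_pool(
    labeled: pd.DataFrame,
    pool_smiles: list[str],
    cfg: RunConfig,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """One-shot Stage 2: score a user-supplied pool against labeled data.

    Fits the surrogate, draws L joint posterior samples, runs qPMHI and
    returns the acquisition table (p_max_hvi, p_pareto_member, selected).
    """
    minmax = MinMaxSpec(cfg.directions)
    names = cfg.objective_names
    featurizer = FEATURIZERS[cfg.featurizer]
    known = set(labeled["smiles"])
    pool_smiles = [s for s in pool_smiles if s not in known]
    if not pool_smiles:
        raise ValueError("pool is empty after removing already-labeled molecules")
    Y = minmax.apply(labeled[names].to_numpy(dtype=float))
    state = ParetoState.from_observations(Y, eps_ref=cfg.eps_ref)
    model = sg.fit(featurizer(labeled["smiles"].tolist()), Y)
    seed = cfg.seed if seed is None else seed
    draws = sg.sample_joint(model, featurizer(pool_smiles), cfg.L, seed)
    result = estimate_pmhi(draws, state)
    select_batch(result, min(cfg.q, len(pool_smiles)))
    return pd.DataFrame(
        {
            "smiles": pool_smiles,
            "p_max_hvi": result.p_max_hvi,
            "p_pareto_member": result.p_pareto_member,
            "selected": np.isin(np.arange(len(pool_smiles)), result.selected).astype(int),
        }
    )
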