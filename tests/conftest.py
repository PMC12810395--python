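"""Shared fixtures and independent brute-force oracles for the suite."""

from __future__ import annotations

import numpy as np
import pytest

from qpmhi.pareto import ParetoState
from qpmhi.surrogate import PosteriorDraws


def brute_force_front(points: np.ndarray) -> np.ndarray:
    """Independent O(n^2) all-pairs dominance scan (sorted rows)."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    keep = []
    for i, p in enumerate(pts):
        dominated = False
        for j, q in enumerate(pts):
            if i != j and np.all(q >= p) and np.any(q > p):
                dominated = True
                break
        if not dominated:
            keep.append(p)
    return np.array(sorted(map(tuple, keep)))


def grid_mc_hypervolume(front, r, n_samples: int = 1_000_000, seed: int = 0):
    """Uniform Monte-Carlo hypervolume oracle; returns (estimate, std_error)."""
    front = np.asarray(front, dtype=float)
    r = np.asarray(r, dtype=float)
    upper = front.max(axis=0)
    box = float(np.prod(upper - r))
    rng = np.random.default_rng(seed)
    u = rng.random((n_samples, front.shape[1])) * (upper - r) + r
    inside = np.zeros(n_samples, dtype=bool)
    for y in front:
        inside |= np.all(u <= y, axis=1)
    p = inside.mean()
    se = box * np.sqrt(max(p * (1 - p), 1e-12) / n_samples)
    return box * p, se


def brute_force_hvi(point, state: ParetoState) -> float:
    """HVI via full hypervolume recomputation (no incremental shortcut)."""
    from qpmhi.pareto import hypervolume

    point = np.maximum(np.asarray(point, dtype=float), state.ref_point)
    joint = np.vstack([state.front, point[None, :]])
    return hypervolume(joint, state.ref_point) - hypervolume(state.front, state.ref_point)


def make_draws(samples: np.ndarray, seed: int = 0) -> PosteriorDraws:
    """Wrap a raw (L, N, M) array as PosteriorDraws."""
    return PosteriorDraws(samples=np.asarray(samples, dtype=float), seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_point_state() -> ParetoState:
    """Front {(1,2),(2,1)} with reference (0,0); HV = 3."""
    return ParetoState(front=[[1.0, 2.0], [2.0, 1.0]], ref_point=[0.0, 0.0])


@pytest.fixture
def toy_smiles() -> list[str]:
    return [
        "CCO", "CCN", "c1ccccc1", "CC(=O)O", "CCCC", "CCOC",
        "CC#N", "CCS", "CCCO", "CCCN", "CC(C)O", "CC(C)N",
    ]
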