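"""Pareto dominance, front maintenance, and hypervolume computation.

All objectives are handled internally in maximization orientation; any
minimized objective is negated once at ingestion (see :class:`MinMaxSpec`).
The hypervolume ``HV(P; r)`` of a front ``P`` with respect to a dominated
reference point ``r`` is the Lebesgue measure of the union of boxes
``[r, y]`` for ``y`` in ``P``.  Exact algorithms are used for M = 2
(sorted sweep) and M = 3 (dimension-sweep recursion); M >= 4 falls back to
a Monte-Carlo estimate with a documented relative tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MinMaxSpec",
    "ParetoState",
    "dominates",
    "pareto_front",
    "hypervolume",
    "hvi",
    "hvi_batch",
    "relative_hvi",
]

#: Relative tolerance documented for the M >= 4 Monte-Carlo fallback.
MC_FALLBACK_RTOL = 1e-2
_MC_FALLBACK_SAMPLES = 200_000


@dataclass(frozen=True)
class MinMaxSpec:
    """Per-objective optimization directions, applied once at ingestion.

    Minimized objectives are negated on load so that every downstream
    computation is pure maximization; ``restore`` undoes the flip for
    user-facing output.
    """

    directions: tuple[str, ...]

    def __post_init__(self) -> None:
        for d in self.directions:
            if d not in ("maximize", "minimize"):
                raise ValueError(f"direction must be maximize/minimize, got {d!r}")

    @property
    def signs(self) -> np.ndarray:
        return np.array([1.0 if d == "maximize" else -1.0 for d in self.directions])

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Map raw objective values to internal maximization orientation."""
        return np.asarray(values, dtype=float) * self.signs

    def restore(self, values: np.ndarray) -> np.ndarray:
        """Map internal values back to the user's orientation."""
        return np.asarray(values, dtype=float) * self.signs


def _check_points(points: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D array of shape (n, M)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("objective vectors must be finite")
    return pts


def dominates(a, b) -> bool:
    """True iff ``a`` Pareto-dominates ``b``.

    ``a`` dominates ``b`` when it is at least as good in every objective and
    strictly better in at least one (maximization orientation).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return bool(np.all(a >= b) and np.any(a > b))


def pareto_front(points) -> np.ndarray:
    """Maximal nondominated subset of ``points`` (duplicates collapsed).

    Returns the front as an (k, M) array in first-appearance order of the
    surviving representatives.  Empty input yields an empty (0, M) array.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, pts.shape[-1] if pts.ndim == 2 else 0)
    pts = _check_points(pts)
    # collapse exact duplicates, keeping first occurrence
    _, first = np.unique(pts, axis=0, return_index=True)
    pts = pts[np.sort(first)]
    n = len(pts)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        if not keep[i]:
            continue
        ge = np.all(pts >= pts[i], axis=1)
        gt = np.any(pts > pts[i], axis=1)
        if np.any(ge & gt & keep):
            keep[i] = False
    return pts[keep]


def _hv_2d(front: np.ndarray, r: np.ndarray) -> float:
    # front assumed nondominated and >= r componentwise
    if len(front) == 0:
        return 0.0
    order = np.argsort(front[:, 0])
    f = front[order]  # x ascending => y descending on a nondominated set
    x_prev = r[0]
    area = 0.0
    for x, y in f:
        area += (x - x_prev) * (y - r[1])
        x_prev = x
    return float(area)


def _hv_3d(front: np.ndarray, r: np.ndarray) -> float:
    # dimension sweep: slice along the third axis at each distinct height
    if len(front) == 0:
        return 0.0
    order = np.argsort(-front[:, 2])
    f = front[order]
    zs = np.append(f[:, 2], r[2])
    vol = 0.0
    for i in range(len(f)):
        dz = zs[i] - zs[i + 1]
        if dz <= 0:
            continue
        slab = pareto_front(f[: i + 1, :2])
        vol += _hv_2d(slab, r[:2]) * dz
    return float(vol)


def _hv_mc(front: np.ndarray, r: np.ndarray, seed: int = 0) -> float:
    upper = front.max(axis=0)
    span = upper - r
    if np.any(span <= 0):
        return 0.0
    rng = np.random.default_rng(seed)
    u = rng.random((_MC_FALLBACK_SAMPLES, front.shape[1])) * span + r
    dominated = np.zeros(len(u), dtype=bool)
    for y in front:
        dominated |= np.all(u <= y, axis=1)
    return float(dominated.mean() * np.prod(span))


def hypervolume(front, r) -> float:
    """Hypervolume of ``front`` with respect to reference point ``r``.

    Points not weakly dominating ``r`` are clipped out with a warning.
    Exact for M in {2, 3} (and trivially M = 1); Monte-Carlo fallback with
    relative tolerance ~1e-2 for M >= 4.
    """
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("reference point must be finite")
    front = np.asarray(front, dtype=float)
    if front.size == 0:
        return 0.0
    front = _check_points(front)
    if front.shape[1] != r.shape[0]:
        raise ValueError("front/reference dimension mismatch")
    ok = np.all(front >= r, axis=1)
    if not np.all(ok):
        warnings.warn(
            f"{int((~ok).sum())} front point(s) below the reference point were clipped out",
            stacklevel=2,
        )
        front = front[ok]
        if len(front) == 0:
            return 0.0
    front = pareto_front(front)
    m = front.shape[1]
    if m == 1:
        return float(front.max() - r[0])
    if m == 2:
        return _hv_2d(front, r)
    if m == 3:
        return _hv_3d(front, r)
    return _hv_mc(front, r)


def _hv_quiet(front, r) -> float:
    # routine state updates legitimately see points below r (fresh labels
    # outside the initial nadir box); clip silently instead of warning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return hypervolume(front, r)


@dataclass
class ParetoState:
    """Incumbent nondominated set plus reference point and cached HV.

    ``front`` is stored in maximization orientation; ``hv_cached`` is kept
    equal to ``hypervolume(front, ref_point)`` after every mutation.
    """

    front: np.ndarray
    ref_point: np.ndarray
    hv_cached: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ref_point = np.asarray(self.ref_point, dtype=float)
        self.front = pareto_front(np.atleast_2d(np.asarray(self.front, dtype=float)))
        if self.hv_cached is None:
            self.hv_cached = _hv_quiet(self.front, self.ref_point)

    @classmethod
    def from_observations(cls, points, eps_ref: float = 0.0) -> "ParetoState":
        """Build a state using the nadir of ``points`` minus ``eps_ref`` as r."""
        pts = _check_points(points)
        r = pts.min(axis=0) - eps_ref
        return cls(front=pts, ref_point=r)

    @property
    def m(self) -> int:
        return int(self.ref_point.shape[0])

    def add_points(self, points) -> None:
        """Merge new observations into the front, updating the cached HV."""
        pts = _check_points(points)
        merged = np.vstack([self.front, pts]) if len(self.front) else pts
        self.front = pareto_front(merged)
        self.hv_cached = _hv_quiet(self.front, self.ref_point)

    def copy(self) -> "ParetoState":
        return ParetoState(self.front.copy(), self.ref_point.copy(), self.hv_cached)


def _staircase(front: np.ndarray, r: np.ndarray):
    """2-D front as staircase segments for vectorized HVI.

    Returns (edges, heights): edges are the f1 breakpoints
    ``r1 = t0 < t1 < ... < tk`` and heights[i] is the dominated-region top
    over f1 in ``(t_i, t_{i+1}]`` — ``heights[k]`` = r2 beyond the last point.
    """
    if len(front) == 0:
        return np.array([r[0]]), np.array([r[1]])
    order = np.argsort(front[:, 0])
    f = front[order]
    edges = np.concatenate([[r[0]], f[:, 0]])
    heights = np.concatenate([f[:, 1], [r[1]]])
    return edges, heights


def hvi_batch(points, state: ParetoState) -> np.ndarray:
    """Hypervolume improvement of each point against a fixed front.

    Candidate coordinates below the reference point are clipped to it, so
    the result is well defined and nonnegative for arbitrary posterior
    draws.  M = 2 is vectorized over candidates via the staircase
    decomposition of the dominated region; other M fall back to per-point
    HV recomputation against the cached front HV.
    """
    pts = _check_points(points)
    r = state.ref_point
    pts = np.maximum(pts, r)  # clip at the box boundary
    if state.m == 2:
        edges, heights = _staircase(state.front, r)
        a = pts[:, 0][:, None]
        b = pts[:, 1][:, None]
        seg_lo = edges[None, :]
        seg_hi = np.concatenate([edges[1:], [np.inf]])[None, :]
        width = np.clip(np.minimum(a, seg_hi) - seg_lo, 0.0, None)
        height = np.clip(b - heights[None, :], 0.0, None)
        return np.einsum("ij,ij->i", width, height)
    base = state.hv_cached
    out = np.empty(len(pts))
    for i, p in enumerate(pts):
        out[i] = hypervolume(np.vstack([state.front, p[None, :]]), r) - base
    return np.maximum(out, 0.0)


def hvi(candidate, state: ParetoState) -> float:
    """HV(front ∪ {candidate}; r) − HV(front; r) for one candidate."""
    return float(hvi_batch(np.atleast_2d(candidate), state)[0])


def relative_hvi(state_t: ParetoState, state_0: ParetoState) -> float:
    """Relative hypervolume improvement (HV_t − HV_0) / HV_0.

    Both states must share the same reference point; the initial HV must be
    strictly positive for the ratio to be defined.
    """
    if not np.allclose(state_t.ref_point, state_0.ref_point):
        raise ValueError("states must share the reference point")
    hv0 = state_0.hv_cached
    if hv0 <= 0:
        raise ValueError("relative HVI undefined: initial hypervolume is zero")
    return (state_t.hv_cached - hv0) / hv0
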