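"""Probabilistic surrogate: independent Gaussian processes per objective.

One GP regressor is fitted per objective (no cross-objective covariance);
features are z-scored per dimension and labels z-scored per objective.
``sample_joint`` draws from the joint multivariate-normal posterior over a
candidate pool — the draws feed the Monte-Carlo acquisition estimator.

The kernel default is an ARD squared-exponential plus a white-noise floor;
the noise floor both reflects the small-but-nonzero observation noise
assumption and breaks hypervolume-improvement ties between candidates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

logger = logging.getLogger(__name__)

__all__ = ["SurrogateModel", "PosteriorDraws", "fit", "sample_joint"]

#: jitter escalation ladder for covariance factorization
_JITTERS = (1e-8, 1e-7, 1e-6, 1e-5, 1e-4)
#: exact joint sampling cap; larger pools are sampled in independent chunks
DEFAULT_POOL_CAP = 5000
#: observation-noise floor on the standardized label scale
NOISE_FLOOR = 1e-6


@dataclass
class PosteriorDraws:
    """L x N x M joint posterior samples over a candidate pool."""

    samples: np.ndarray  # (L, N, M), original objective scale
    seed: int
    pool_index: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 3:
            raise ValueError("samples must have shape (L, N, M)")
        if self.pool_index is None:
            self.pool_index = np.arange(self.samples.shape[1])

    @property
    def L(self) -> int:
        return self.samples.shape[0]

    @property
    def N(self) -> int:
        return self.samples.shape[1]

    @property
    def M(self) -> int:
        return self.samples.shape[2]


class SurrogateModel:
    """M independent GP regressors over standardized features/labels."""

    def __init__(self, gps, x_mean, x_std, y_mean, y_std):
        self.gps = gps
        self.x_mean = x_mean
        self.x_std = x_std
        self.y_mean = y_mean
        self.y_std = y_std

    @property
    def m(self) -> int:
        return len(self.gps)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_std

    def predict(self, X, return_std: bool = False):
        """Posterior mean (and marginal sd) on the original objective scale."""
        Xs = self._standardize(X)
        means, sds = [], []
        for m, gp in enumerate(self.gps):
            if return_std:
                mu, sd = gp.predict(Xs, return_std=True)
                sds.append(sd * self.y_std[m])
            else:
                mu = gp.predict(Xs)
            means.append(mu * self.y_std[m] + self.y_mean[m])
        mean = np.column_stack(means)
        if return_std:
            return mean, np.column_stack(sds)
        return mean

    def lengthscales(self, m: int) -> np.ndarray:
        """Fitted ARD lengthscales of objective ``m`` (standardized-feature scale)."""
        return np.atleast_1d(self.gps[m].kernel_.k1.k2.length_scale)


def fit(
    X,
    Y,
    n_restarts: int = 1,
    random_state: int = 0,
    optimize: bool = True,
) -> SurrogateModel:
    """Fit one ARD-RBF Gaussian process per objective column of ``Y``.

    Features are z-scored per dimension (constant dimensions get unit
    scale); labels are z-scored per objective.  Hyperparameters are chosen
    by marginal-likelihood maximization; a small white-noise floor is
    always included.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training pairs")
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite objective labels")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")

    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0)
    if np.all(x_std == 0):
        raise ValueError("degenerate features: zero variance in every dimension")
    x_std = np.where(x_std == 0, 1.0, x_std)
    Xs = (X - x_mean) / x_std

    y_mean = Y.mean(axis=0)
    y_std = Y.std(axis=0)
    y_std = np.where(y_std == 0, 1.0, y_std)
    Ys = (Y - y_mean) / y_std

    d = X.shape[1]
    gps = []
    for m in range(Y.shape[1]):
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
            length_scale=np.ones(d), length_scale_bounds=(1e-2, 1e3)
        ) + WhiteKernel(1e-4, (NOISE_FLOOR, 1e1))
        gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=NOISE_FLOOR,
            optimizer="fmin_l_bfgs_b" if optimize else None,
            n_restarts_optimizer=n_restarts if optimize else 0,
            normalize_y=False,
            random_state=random_state + m,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(Xs, Ys[:, m])
        gps.append(gp)
    return SurrogateModel(gps, x_mean, x_std, y_mean, y_std)


def _sample_chunk(model, Xs, L, rng):
    """Joint MVN draws for one pool chunk; (L, n, M) standardized scale."""
    n = Xs.shape[0]
    out = np.empty((L, n, model.m))
    for m, gp in enumerate(model.gps):
        mu, cov = gp.predict(Xs, return_cov=True)
        cov = np.asarray(cov)
        chol = None
        for jitter in _JITTERS:
            try:
                chol = np.linalg.cholesky(cov + jitter * np.eye(n))
                break
            except np.linalg.LinAlgError:
                continue
        if chol is None:
            raise np.linalg.LinAlgError(
                f"posterior covariance factorization failed for pool of size {n} "
                f"after jitter escalation to {_JITTERS[-1]:g}"
            )
        z = rng.standard_normal((L, n))
        out[:, :, m] = mu[None, :] + z @ chol.T
    return out


def sample_joint(
    model: SurrogateModel,
    pool,
    L: int,
    seed: int,
    pool_cap: int = DEFAULT_POOL_CAP,
) -> PosteriorDraws:
    """Draw L joint posterior samples of all objectives over ``pool``.

    Objectives are sampled independently of one another; within an
    objective the N pool points are jointly multivariate normal.  Pools
    larger than ``pool_cap`` are sampled in independent chunks with a
    logged warning (the joint structure then holds only within chunks).
    Draws are de-standardized back to the original objective scale and are
    reproducible given ``seed``.
    """
    pool = np.asarray(pool, dtype=float)
    if pool.ndim != 2 or pool.shape[0] == 0:
        raise ValueError("pool must be a nonempty (N, d) feature array")
    if L < 1:
        raise ValueError("L must be >= 1")
    Xs = model._standardize(pool)
    n = Xs.shape[0]
    rng = np.random.default_rng(seed)
    if n <= pool_cap:
        raw = _sample_chunk(model, Xs, L, rng)
    else:
        logger.warning(
            "pool size %d exceeds joint-sampling cap %d; sampling in independent chunks",
            n,
            pool_cap,
        )
        parts = [
            _sample_chunk(model, Xs[i : i + pool_cap], L, rng)
            for i in range(0, n, pool_cap)
        ]
        raw = np.concatenate(parts, axis=1)
    samples = raw * model.y_std[None, None, :] + model.y_mean[None, None, :]
    return PosteriorDraws(samples=samples, seed=seed)
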