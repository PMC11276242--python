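"""Core types and exact evaluation of the eSPA-Markov objective.

eSPA-Markov classifies noisy, time-ordered observations by jointly learning

* a fuzzy discretization of feature space into ``K`` clusters, each carrying
  per-dimension Gaussian emission parameters (mu, sigma),
* an entropy-regularized probability vector ``W`` over the ``D`` features,
* a column-stochastic Bayesian classifier ``Lambda`` mapping clusters to the
  ``M`` labels, and
* a column-stochastic affiliation matrix ``Gamma`` (K x T) whose time
  evolution is penalized for deviating from a Markov transition prior ``P``.

The scalarized objective minimized here (all terms in nats) is

    eps_L/T * sum_{d,k,t} W_d Gamma_{k,t} nll(X_{d,t}; mu_{d,k}, sigma_{d,k})
  + eps_E   * sum_d W_d log W_d
  - eps_CL/T * sum_{m,t} Pi_{m,t} sum_k log(Lambda_{m,k}) Gamma_{k,t}
  + 1/T * sum_{t<T} sum_{k1} (Gamma_{k1,t+1} - sum_{k2} P_{k1,k2} Gamma_{k2,t})^2

where the classification term is the Jensen-relaxed Kullback-Leibler
discrepancy (log moved inside the cluster sum), which is the form that admits
closed-form Lambda and W updates.  With ``P`` equal to the identity the last
term reduces to a plain squared-difference (H1) persistence penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "SIGMA_FLOOR",
    "FEASIBILITY_TOL",
    "HyperParams",
    "GaussianCentroids",
    "LossBreakdown",
    "gaussian_nll",
    "nll_tensor",
    "markov_penalty",
    "eval_loss",
    "validate_feasible",
    "feasibility_errors",
    "zscore_rows",
]

#: Lower bound applied to every Gaussian standard deviation (data units).
#: The negative log-likelihood diverges as sigma -> 0, so collapsed clusters
#: are clipped here instead of producing infinities.
SIGMA_FLOOR = 1e-6

#: Tolerance used when checking box and normalization constraints.
FEASIBILITY_TOL = 1e-8

_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class HyperParams:
    """Scalarization weights and cluster count of the objective.

    Parameters
    ----------
    eps_L : float
        Weight of the Gaussian likelihood term (>= 0).
    eps_E : float
        Entropy regularization strength for the feature weights (> 0; the
        W update divides by it).
    eps_CL : float
        Weight of the classification (KL) term; 0 switches the model into
        pure prediction mode where labels are ignored.
    K : int
        Number of clusters (>= 1).
    """

    eps_L: float
    eps_E: float
    eps_CL: float
    K: int

    def __post_init__(self) -> None:
        if not (self.eps_L >= 0.0 and math.isfinite(self.eps_L)):
            raise ValueError(f"eps_L must be finite and >= 0, got {self.eps_L}")
        if not (self.eps_E > 0.0 and math.isfinite(self.eps_E)):
            raise ValueError(f"eps_E must be finite and > 0, got {self.eps_E}")
        if not (self.eps_CL >= 0.0 and math.isfinite(self.eps_CL)):
            raise ValueError(f"eps_CL must be finite and >= 0, got {self.eps_CL}")
        if not (isinstance(self.K, (int, np.integer)) and self.K >= 1):
            raise ValueError(f"K must be a positive integer, got {self.K}")


@dataclass
class GaussianCentroids:
    """Per-cluster, per-dimension Gaussian emission parameters.

    Both arrays have shape (D, K); ``sigma`` entries are floored at
    :data:`SIGMA_FLOOR`.
    """

    mu: NDArray[np.float64]
    sigma: NDArray[np.float64]

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape or self.mu.ndim != 2:
            raise ValueError(
                f"mu and sigma must be matching (D, K) matrices, got "
                f"{self.mu.shape} and {self.sigma.shape}"
            )
        if not (np.isfinite(self.mu).all() and np.isfinite(self.sigma).all()):
            raise ValueError("centroid parameters must be finite")
        if (self.sigma < SIGMA_FLOOR).any():
            raise ValueError(f"sigma entries must be >= {SIGMA_FLOOR}")

    @property
    def D(self) -> int:
        return self.mu.shape[0]

    @property
    def K(self) -> int:
        return self.mu.shape[1]


@dataclass(frozen=True)
class LossBreakdown:
    """The four addends of the objective plus their total, in nats."""

    likelihood_term: float
    entropy_term: float
    classification_term: float
    markov_term: float
    total: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if np.isnan(self.total):
            object.__setattr__(
                self,
                "total",
                self.likelihood_term
                + self.entropy_term
                + self.classification_term
                + self.markov_term,
            )


def gaussian_nll(x: ArrayLike, mu: ArrayLike, sigma: ArrayLike) -> np.ndarray | float:
    """Negative log-likelihood of a univariate Gaussian, elementwise.

    ``0.5*log(2*pi*sigma^2) + (x - mu)^2 / (2*sigma^2)``; raises on any
    non-positive ``sigma``.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if (sigma <= 0.0).any():
        raise ValueError("sigma must be strictly positive")
    z = (x - mu) / sigma
    out = _HALF_LOG_2PI + np.log(sigma) + 0.5 * z * z
    return out if out.ndim else float(out)


def nll_tensor(
    X: NDArray[np.float64], mu: NDArray[np.float64], sigma: NDArray[np.float64]
) -> NDArray[np.float64]:
    """Gaussian NLL of every data point under every cluster, shape (D, K, T).

    ``X`` is (D, T); ``mu``/``sigma`` are (D, K).
    """
    if (sigma <= 0.0).any():
        raise ValueError("sigma must be strictly positive")
    z = (X[:, None, :] - mu[:, :, None]) / sigma[:, :, None]
    return _HALF_LOG_2PI + np.log(sigma)[:, :, None] + 0.5 * z * z


def _xlogx(w: NDArray[np.float64]) -> NDArray[np.float64]:
    """w*log(w) with the convention 0*log(0) = 0."""
    out = np.zeros_like(w)
    pos = w > 0.0
    out[pos] = w[pos] * np.log(w[pos])
    return out


def markov_penalty(gamma: ArrayLike, P: ArrayLike, T: int | None = None) -> float:
    """Markov smoothness penalty of an affiliation path.

    ``(1/T) * sum_{t=1..T-1} || Gamma[:, t+1] - P @ Gamma[:, t] ||^2``.
    For ``P = I`` this is the H1-style penalty on affiliation changes.
    ``T`` defaults to the number of columns of ``gamma`` (it is exposed so the
    same 1/T scale can be kept when evaluating on a sub-path).
    """
    gamma = np.asarray(gamma, dtype=float)
    P = np.asarray(P, dtype=float)
    K = gamma.shape[0]
    if P.shape != (K, K):
        raise ValueError(f"P must be ({K}, {K}) to match Gamma, got {P.shape}")
    if T is None:
        T = gamma.shape[1]
    if gamma.shape[1] < 2:
        return 0.0
    diff = gamma[:, 1:] - P @ gamma[:, :-1]
    return float(np.sum(diff * diff) / T)


def eval_loss(
    X: ArrayLike,
    Pi: ArrayLike | None,
    gamma: ArrayLike,
    theta: GaussianCentroids,
    lam: ArrayLike | None,
    W: ArrayLike,
    P: ArrayLike | None,
    hp: HyperParams,
) -> LossBreakdown:
    """Evaluate the objective and each of its four terms.

    ``Pi`` and ``lam`` may be ``None`` only when ``hp.eps_CL == 0``
    (prediction mode).  ``P`` defaults to the identity.  Infeasible
    ``gamma``/``lam``/``W`` raise a ``ValueError`` naming the violated
    constraint.  A zero entry of ``lam`` carrying positive ``Pi * gamma``
    weight yields ``classification_term = +inf`` (never an exception).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    W = np.asarray(W, dtype=float).ravel()
    D, T = X.shape
    K = gamma.shape[0]
    if gamma.shape[1] != T:
        raise ValueError(f"Gamma has {gamma.shape[1]} columns but X has T={T}")
    if theta.mu.shape != (D, K):
        raise ValueError(f"centroids shaped {theta.mu.shape}, expected ({D}, {K})")
    if W.shape != (D,):
        raise ValueError(f"W has length {W.shape[0]}, expected D={D}")
    if P is None:
        P = np.eye(K)
    for name, obj in (("Gamma", gamma), ("W", W)):
        errs = feasibility_errors(obj)
        if errs:
            raise ValueError(f"{name} infeasible: " + "; ".join(errs))

    ell = nll_tensor(X, theta.mu, theta.sigma)
    likelihood = hp.eps_L / T * float(np.einsum("d,kt,dkt->", W, gamma, ell))
    entropy = hp.eps_E * float(_xlogx(W).sum())

    if hp.eps_CL == 0.0:
        classification = 0.0
    else:
        if Pi is None or lam is None:
            raise ValueError("Pi and Lambda are required when eps_CL > 0")
        Pi = np.atleast_2d(np.asarray(Pi, dtype=float))
        lam = np.atleast_2d(np.asarray(lam, dtype=float))
        errs = feasibility_errors(Pi)
        if errs:
            raise ValueError("Pi infeasible: " + "; ".join(errs))
        errs = feasibility_errors(lam)
        if errs:
            raise ValueError("Lambda infeasible: " + "; ".join(errs))
        if Pi.shape[1] != T or lam.shape != (Pi.shape[0], K):
            raise ValueError("Pi/Lambda dimensions inconsistent with X and Gamma")
        # weight_{m,k} = sum_t Pi_{m,t} Gamma_{k,t}; zero weight kills log(0).
        weight = Pi @ gamma.T
        pos = weight > 0.0
        if (pos & (lam <= 0.0)).any():
            classification = math.inf
        else:
            classification = -hp.eps_CL / T * float(
                np.sum(weight[pos] * np.log(lam[pos]))
            )

    markov = markov_penalty(gamma, P, T)
    return LossBreakdown(likelihood, entropy, classification, markov)


def feasibility_errors(obj: ArrayLike, tol: float = FEASIBILITY_TOL) -> list[str]:
    """Diagnostics for the stochasticity constraints; empty list = feasible.

    A 1-D array is treated as a probability vector (entries in [0, 1],
    summing to 1); a 2-D array as a column-stochastic matrix (every column a
    probability vector).
    """
    arr = np.asarray(obj, dtype=float)
    errs: list[str] = []
    if not np.isfinite(arr).all():
        return ["non-finite entries"]
    if (arr < -tol).any():
        errs.append(f"negative entries (min {arr.min():.3g})")
    if (arr > 1.0 + tol).any():
        errs.append(f"entries above one (max {arr.max():.3g})")
    sums = arr.sum() if arr.ndim == 1 else arr.sum(axis=0)
    dev = np.max(np.abs(np.asarray(sums) - 1.0))
    if dev > tol:
        kind = "vector sum" if arr.ndim == 1 else "column sums"
        errs.append(f"{kind} deviate from one by {dev:.3g}")
    return errs


def validate_feasible(obj: ArrayLike, tol: float = FEASIBILITY_TOL) -> bool:
    """True iff box and normalization constraints hold within ``tol``."""
    return not feasibility_errors(obj, tol=tol)


def zscore_rows(
    X: ArrayLike,
    stats: tuple[NDArray[np.float64], NDArray[np.float64]] | None = None,
) -> tuple[NDArray[np.float64], tuple[NDArray[np.float64], NDArray[np.float64]]]:
    """Standardize each feature (row) to zero mean, unit variance.

    Returns the standardized matrix and the ``(mean, sd)`` statistics used,
    so that held-out data can be transformed with the training statistics by
    passing ``stats``.  Constant rows are left centered with sd clamped to 1.
    The Gaussian likelihood term rewards low-variance features regardless of
    their class information, so fitting on a common per-feature scale is the
    pipeline default upstream of :func:`espamarkov.learning.fit`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if stats is None:
        mean = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd = np.where(sd < 1e-12, 1.0, sd)
    else:
        mean, sd = stats
        mean = np.asarray(mean, dtype=float).reshape(-1, 1)
        sd = np.asarray(sd, dtype=float).reshape(-1, 1)
    return (X - mean) / sd, (mean, sd)
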