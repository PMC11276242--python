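"""Fitting: analytic subspace steps, the iterative loop, one-shot learning.

The objective is minimized by block-coordinate descent.  Three of the four
blocks have closed-form conditional minimizers:

* ``(mu, sigma)`` -- affiliation-weighted means and standard deviations
  (a fuzzy, spherical Gaussian-mixture M-step),
* ``Lambda`` -- column-normalized co-occurrence of labels and affiliations,
* ``W`` -- a softmax of the per-dimension likelihood errors at temperature
  ``T * eps_E``,

while the ``Gamma`` block is the convex QP of :mod:`espamarkov.qp_gamma`.
Each outer iteration runs Gamma -> (mu, sigma) -> Lambda -> W; every step is
a conditional minimizer (Gamma warm-starts at the incumbent, so its inexact
solve cannot increase the objective), hence the total loss is monotonically
non-increasing.

When clusters and labels are in bijection (K = M) the whole model can be
learned in one shot, without any outer iteration: the training affiliations
are the labels themselves, the classifier is the identity, the Gaussian
parameters follow in closed form, and the (eps_E, eps_L) pair is selected on
a grid by how well the prediction-mode Gamma solve reconstructs the training
labels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray

from .model_core import (
    SIGMA_FLOOR,
    GaussianCentroids,
    HyperParams,
    LossBreakdown,
    eval_loss,
    nll_tensor,
    validate_feasible,
    zscore_rows,
)
from .qp_gamma import MarkovQP, build_H, build_linear_term, project_simplex_columns, spgqp_solve
from .synth_data import auc_score, triple_split

__all__ = [
    "FittedModel",
    "GridSpec",
    "GridSearchResult",
    "update_mu_sigma",
    "update_lambda",
    "update_w",
    "fit",
    "predict",
    "fit_oneshot",
    "grid_search",
]


@dataclass
class FittedModel:
    """A trained eSPA-Markov model plus fit diagnostics."""

    theta: GaussianCentroids
    lam: NDArray[np.float64]
    W: NDArray[np.float64]
    P: NDArray[np.float64]
    hp: HyperParams
    loss: LossBreakdown
    gamma_train: NDArray[np.float64]
    loss_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    n_starts: int = 1
    seed: int | None = None
    feature_stats: tuple[NDArray[np.float64], NDArray[np.float64]] | None = None

    @property
    def D(self) -> int:
        return self.theta.D

    @property
    def K(self) -> int:
        return self.theta.K

    @property
    def M(self) -> int:
        return self.lam.shape[0]


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid; defaults are the method's standard search grid."""

    eps_CL: tuple[float, ...] = (1e-4, 1e-3, 1e-2)
    eps_L: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0, 2.0, 5.0, 10.0)
    eps_E: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1)
    K: tuple[int, ...] = (2, 3, 5)

    def __post_init__(self) -> None:
        for name in ("eps_CL", "eps_L", "eps_E", "K"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"grid for {name} must be nonempty")
        if any(e <= 0 for e in self.eps_E):
            raise ValueError("eps_E grid values must be > 0")
        if any(e < 0 for e in self.eps_L) or any(e < 0 for e in self.eps_CL):
            raise ValueError("eps_L / eps_CL grid values must be >= 0")
        if any(k < 1 for k in self.K):
            raise ValueError("K grid values must be >= 1")

    @property
    def n(self) -> int:
        return len(self.eps_CL) * len(self.eps_L) * len(self.eps_E) * len(self.K)


def update_mu_sigma(
    X: ArrayLike,
    gamma: ArrayLike,
    sigma_floor: float = SIGMA_FLOOR,
    rng: np.random.Generator | None = None,
) -> GaussianCentroids:
    """Conditional minimizer of the likelihood term over (mu, sigma).

    Affiliation-weighted per-dimension means and (population) standard
    deviations.  A cluster with vanishing affiliation mass is reseeded at a
    randomly chosen data column with sigma set to the per-dimension data SD.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    D, T = X.shape
    K = gamma.shape[0]
    mass = gamma.sum(axis=1)  # (K,)
    empty = mass < 1e-12
    safe_mass = np.where(empty, 1.0, mass)
    mu = (X @ gamma.T) / safe_mass  # (D, K)
    var = np.empty((D, K))
    for k in range(K):
        diff = X - mu[:, [k]]
        var[:, k] = (gamma[k] * diff * diff).sum(axis=1) / safe_mass[k]
    sigma = np.sqrt(var)
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} cluster(s) lost all affiliation mass; reseeding",
            stacklevel=2,
        )
        if rng is None:
            rng = np.random.default_rng(0)
        data_sd = X.std(axis=1)
        for k in np.flatnonzero(empty):
            mu[:, k] = X[:, rng.integers(T)]
            sigma[:, k] = data_sd
    return GaussianCentroids(mu, np.maximum(sigma, sigma_floor))


def update_lambda(Pi: ArrayLike, gamma: ArrayLike) -> NDArray[np.float64]:
    """Conditional minimizer of the classification term over Lambda.

    ``Lambda[m, k] proportional to sum_t Pi[m, t] Gamma[k, t]``, normalized so
    each column sums to one; a column with no mass becomes uniform.
    """
    Pi = np.atleast_2d(np.asarray(Pi, dtype=float))
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    hat = Pi @ gamma.T  # (M, K)
    col = hat.sum(axis=0)
    M = hat.shape[0]
    lam = np.where(col > 0.0, hat / np.where(col > 0.0, col, 1.0), 1.0 / M)
    return lam


def update_w(
    X: ArrayLike,
    gamma: ArrayLike,
    theta: GaussianCentroids,
    hp: HyperParams,
) -> NDArray[np.float64]:
    """Conditional minimizer of likelihood + entropy over the weights W.

    Softmax of minus the affiliation-weighted NLL per dimension at
    temperature ``T * eps_E`` (max-subtracted for stability).  eps_L scales
    both the likelihood and the implied temperature, so it enters here only
    through eps_L/eps_E; eps_L = 0 yields the uniform vector.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    T = X.shape[1]
    ell = nll_tensor(X, theta.mu, theta.sigma)
    b = np.einsum("kt,dkt->d", gamma, ell)  # (D,)
    logits = -(hp.eps_L * b) / (T * hp.eps_E)
    logits -= logits.max()
    w = np.exp(logits)
    return w / w.sum()


def _random_affiliation(K: int, T: int, rng: np.random.Generator) -> NDArray[np.float64]:
    """Uniform random entries per column, projected onto the simplex."""
    return project_simplex_columns(rng.uniform(size=(K, T)))


def fit(
    X: ArrayLike,
    Pi: ArrayLike,
    hp: HyperParams,
    P: ArrayLike | None = None,
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_outer: int = 200,
    qp_tol: float | None = None,
    qp_max_iter: int | None = None,
) -> FittedModel:
    """Fit by multi-start block-coordinate descent.

    Each restart draws a random feasible affiliation (seeded deterministically
    from ``(seed, restart)``), initializes the remaining blocks from it with
    their analytic updates, then iterates
    Gamma -> (mu, sigma) -> Lambda -> W until the relative total-loss decrease
    drops below ``tol`` or ``max_outer`` iterations.  The restart with the
    lowest final loss wins.

    The inner Gamma solves use a looser stopping tolerance than a standalone
    solve (``qp_tol`` default ``1e-8 * K * T``): they are warm-started and
    repeated every outer iteration, so only the final objective, not the
    iterate itself, needs high precision.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Pi = np.atleast_2d(np.asarray(Pi, dtype=float))
    D, T = X.shape
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite entries")
    if T < 2:
        raise ValueError("T >= 2 is required for a Markov-regularized fit")
    if Pi.shape[1] != T:
        raise ValueError("Pi must have the same number of columns as X")
    if not validate_feasible(Pi, tol=1e-6):
        raise ValueError("Pi must be column-stochastic")
    K = hp.K
    if K > T:
        raise ValueError(f"K={K} clusters exceed T={T} data points")
    if P is None:
        P = np.eye(K)
    P = np.asarray(P, dtype=float)
    H = build_H(P, K, T)
    if qp_tol is None:
        qp_tol = 1e-8 * K * T

    best: FittedModel | None = None
    for r in range(n_starts):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
        gamma = _random_affiliation(K, T, rng)
        theta = update_mu_sigma(X, gamma, rng=rng)
        lam = update_lambda(Pi, gamma)
        W = update_w(X, gamma, theta, hp)
        loss = eval_loss(X, Pi, gamma, theta, lam, W, P, hp)
        trace = [loss.total]
        n_iter = 0
        for n_iter in range(1, max_outer + 1):
            b = build_linear_term(X, Pi, theta, lam, W, hp)
            qp = MarkovQP(H, b, K, T)
            gamma, _ = spgqp_solve(qp, gamma, tol=qp_tol, max_iter=qp_max_iter)
            theta = update_mu_sigma(X, gamma, rng=rng)
            lam = update_lambda(Pi, gamma)
            W = update_w(X, gamma, theta, hp)
            loss = eval_loss(X, Pi, gamma, theta, lam, W, P, hp)
            trace.append(loss.total)
            prev, cur = trace[-2], trace[-1]
            if prev - cur < tol * max(1.0, abs(prev)):
                break
        candidate = FittedModel(
            theta=theta,
            lam=lam,
            W=W,
            P=P,
            hp=hp,
            loss=loss,
            gamma_train=gamma,
            loss_trace=trace,
            iterations=n_iter,
            n_starts=n_starts,
            seed=seed,
        )
        if best is None or candidate.loss.total < best.loss.total:
            best = candidate
    assert best is not None
    return best


def predict(
    model: FittedModel,
    Xtest: ArrayLike,
    tol: float | None = None,
    max_iter: int | None = None,
    seed: int = 0,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Label probabilities for new data: one Gamma solve with eps_CL = 0.

    The affiliation problem is solved on the test stretch with the trained
    Gaussian parameters and feature weights (labels play no role), from a
    seeded random feasible start; predicted label probabilities are then
    ``Pi_hat = Lambda @ Gamma``.  Returns ``(Pi_hat, Gamma)``.
    """
    Xtest = np.atleast_2d(np.asarray(Xtest, dtype=float))
    if model.feature_stats is not None:
        Xtest, _ = zscore_rows(Xtest, stats=model.feature_stats)
    D, T = Xtest.shape
    if D != model.D:
        raise ValueError(f"model expects D={model.D} features, got {D}")
    if T < 2:
        raise ValueError("T >= 2 test points are required")
    K = model.K
    hp_pred = HyperParams(model.hp.eps_L, model.hp.eps_E, 0.0, K)
    H = build_H(model.P, K, T)
    b = build_linear_term(Xtest, None, model.theta, None, model.W, hp_pred)
    qp = MarkovQP(H, b, K, T)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xFEED,)))
    gamma0 = _random_affiliation(K, T, rng)
    gamma, _ = spgqp_solve(qp, gamma0, tol=tol, max_iter=max_iter)
    pi_hat = model.lam @ gamma
    return pi_hat, gamma


def fit_oneshot(
    Xtrain: ArrayLike,
    Pitrain: ArrayLike,
    grid: GridSpec | None = None,
    P: ArrayLike | None = None,
    qp_tol: float | None = None,
    qp_max_iter: int | None = None,
) -> tuple[FittedModel, tuple[float, float]]:
    """Direct one-shot learning when clusters and labels are in bijection.

    Requires ``K = M`` and every label present.  Sets the training
    affiliations equal to the labels and the classifier to the identity;
    the Gaussian parameters follow from one analytic update.  For each
    ``eps_E`` on the grid the optimal ``W`` is computed in closed form; for
    each ``(eps_E, eps_L)`` pair a single prediction-mode Gamma solve is run
    on the training data, and the pair whose solution best reconstructs the
    training labels (squared Frobenius error, ties to the earliest grid
    entry) is selected.  No outer iteration takes place.

    Returns the model and the chosen ``(eps_E, eps_L)``.
    """
    X = np.atleast_2d(np.asarray(Xtrain, dtype=float))
    Pi = np.atleast_2d(np.asarray(Pitrain, dtype=float))
    if grid is None:
        grid = GridSpec()
    D, T = X.shape
    M = Pi.shape[0]
    K = M  # bijective cluster <-> label mapping
    if Pi.shape[1] != T:
        raise ValueError("Pitrain must have the same number of columns as Xtrain")
    if not validate_feasible(Pi, tol=1e-6):
        raise ValueError("Pitrain must be column-stochastic")
    if (Pi.sum(axis=1) <= 0.0).any():
        raise ValueError("every label must occur in Pitrain")
    if P is None:
        P = np.eye(K)
    P = np.asarray(P, dtype=float)
    if P.shape != (K, K):
        raise ValueError(
            f"one-shot learning requires a bijective cluster-label mapping: "
            f"P must be ({K}, {K}) = (M, M), got {P.shape}"
        )

    gamma_train = Pi.copy()
    lam = np.eye(K)
    theta = update_mu_sigma(X, gamma_train)
    H = build_H(P, K, T)

    best_err = np.inf
    best_pair: tuple[float, float] | None = None
    best_W: NDArray[np.float64] | None = None
    for eps_E in grid.eps_E:
        for eps_L in grid.eps_L:
            hp_pair = HyperParams(eps_L, eps_E, 0.0, K)
            W = update_w(X, gamma_train, theta, hp_pair)
            b = build_linear_term(X, None, theta, None, W, hp_pair)
            gamma_star, _ = spgqp_solve(
                MarkovQP(H, b, K, T),
                np.full((K, T), 1.0 / K),
                tol=qp_tol,
                max_iter=qp_max_iter,
            )
            err = float(np.sum((Pi - gamma_star) ** 2))
            if err < best_err:  # strict: ties keep the earliest grid entry
                best_err = err
                best_pair = (eps_E, eps_L)
                best_W = W
    assert best_pair is not None and best_W is not None
    eps_E_star, eps_L_star = best_pair
    hp_star = HyperParams(eps_L_star, eps_E_star, 0.0, K)
    loss = eval_loss(X, Pi, gamma_train, theta, lam, best_W, P, hp_star)
    model = FittedModel(
        theta=theta,
        lam=lam,
        W=best_W,
        P=P,
        hp=hp_star,
        loss=loss,
        gamma_train=gamma_train,
        loss_trace=[loss.total],
        iterations=0,
        n_starts=1,
    )
    return model, best_pair


@dataclass
class GridSearchResult:
    """Outcome of a triple-split hyperparameter search."""

    best_model: FittedModel
    table: pd.DataFrame
    best_val_auc: float
    test_auc: float
    split: tuple[NDArray[np.intp], NDArray[np.intp], NDArray[np.intp]]


def _hard_labels(Pi: NDArray[np.float64]) -> NDArray[np.intp]:
    return np.argmax(Pi, axis=0)


def grid_search(
    X: ArrayLike,
    Pi: ArrayLike,
    grid: GridSpec | None = None,
    split: Sequence[NDArray[np.intp]] | None = None,
    seed: int = 0,
    n_starts: int = 10,
    standardize: bool = True,
    P: ArrayLike | None = None,
    positive_label: int = 1,
    **fit_kwargs,
) -> GridSearchResult:
    """Exhaustive hyperparameter search with contiguous triple splitting.

    Every grid combination is fitted on the training block; the model with
    the best validation AUC (score = the positive label's row of the
    predicted probabilities) is selected, and its test AUC reported.  Binary
    labels only.  With ``standardize`` (default) features are z-scored with
    training-block statistics before fitting and prediction.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Pi = np.atleast_2d(np.asarray(Pi, dtype=float))
    if grid is None:
        grid = GridSpec()
    if Pi.shape[0] != 2:
        raise ValueError("grid_search scores AUC and requires exactly 2 labels")
    T = X.shape[1]
    if split is None:
        split = triple_split(T)
    tr, va, te = (np.asarray(s) for s in split)
    labels = _hard_labels(Pi)
    for name, idx in (("training", tr), ("validation", va), ("test", te)):
        if np.unique(labels[idx]).size < 2:
            raise ValueError(f"AUC undefined: {name} split contains a single class")

    Xtr = X[:, tr]
    stats = None
    if standardize:
        Xtr, stats = zscore_rows(Xtr)
    # independent prediction starts for the validation and test blocks: with
    # a weak likelihood signal the predicted affiliation pattern retains a
    # memory of its random start, and reusing one start across adjacent
    # blocks would let validation selection leak into the test score
    val_ss, test_ss = np.random.SeedSequence(seed).spawn(2)
    val_seed = int(val_ss.generate_state(1)[0] % (2**31 - 1))
    test_seed = int(test_ss.generate_state(1)[0] % (2**31 - 1))
    rows = []
    best_model: FittedModel | None = None
    best_val = -np.inf
    combos = itertools.product(grid.eps_CL, grid.eps_L, grid.eps_E, grid.K)
    for eps_CL, eps_L, eps_E, K in combos:
        hp = HyperParams(eps_L, eps_E, eps_CL, K)
        model = fit(Xtr, Pi[:, tr], hp, P=P, n_starts=n_starts, seed=seed, **fit_kwargs)
        model.feature_stats = stats
        pi_val, _ = predict(model, X[:, va], seed=val_seed)
        val_auc = auc_score(pi_val[positive_label], labels[va] == positive_label)
        rows.append(
            {"eps_CL": eps_CL, "eps_L": eps_L, "eps_E": eps_E, "K": K, "val_auc": val_auc}
        )
        if val_auc > best_val:
            best_val = val_auc
            best_model = model
    assert best_model is not None
    pi_te, _ = predict(best_model, X[:, te], seed=test_seed)
    test_auc = auc_score(pi_te[positive_label], labels[te] == positive_label)
    return GridSearchResult(
        best_model=best_model,
        table=pd.DataFrame(rows),
        best_val_auc=best_val,
        test_auc=test_auc,
        split=(tr, va, te),
    )
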