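"""The affiliation (Gamma) step: a convex QP over a product of simplices.

Holding the Gaussian parameters, classifier and feature weights fixed, the
objective is quadratic in the vectorized affiliations ``gamma = vec(Gamma)``:

    f(gamma) = b' gamma + (1/T) gamma' H gamma,

where ``H`` encodes the Markov smoothness penalty and ``b`` collects the
(likelihood and classification) errors of assigning each time point to each
cluster.  The feasible set is the product of T probability simplices (one
per time point), onto which Euclidean projection is cheap, so the problem is
solved with a spectral projected gradient method (SPG-QP): Barzilai-Borwein
step lengths, projection onto the feasible set, and a nonmonotone
line search along the feasible direction.

Vectorization is cluster-major: ``gamma[(k)*T + t] = Gamma[k, t]`` (each
cluster's T time points contiguous), matching the Kronecker structure of H.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from numpy.typing import ArrayLike, NDArray

from .model_core import GaussianCentroids, HyperParams, nll_tensor, validate_feasible

__all__ = [
    "MarkovQP",
    "SolverReport",
    "build_H",
    "build_linear_term",
    "project_simplex_columns",
    "spgqp_solve",
]

#: Finite stand-in for log(0) when a classifier entry is exactly zero but the
#: corresponding label weight is positive: the QP needs finite coefficients,
#: and this penalty is large enough to force zero affiliation mass there.
_LOG_ZERO_PENALTY = -1e6


@dataclass
class MarkovQP:
    """The Gamma-step QP: minimize ``b'g + (1/T) g'Hg`` over simplex columns."""

    H: sp.spmatrix
    b: NDArray[np.float64]
    K: int
    T: int

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float).ravel()
        n = self.K * self.T
        if self.H.shape != (n, n) or self.b.shape != (n,):
            raise ValueError(
                f"H {self.H.shape} / b {self.b.shape} inconsistent with K*T={n}"
            )

    def objective(self, gamma: ArrayLike) -> float:
        g = np.asarray(gamma, dtype=float).ravel()
        return float(self.b @ g + (g @ (self.H @ g)) / self.T)

    def to_coo_text(self) -> str:
        """Sparse (row, col, value) text dump of H, for debugging."""
        coo = self.H.tocoo()
        lines = [
            f"{i} {j} {float(v)!r}" for i, j, v in zip(coo.row, coo.col, coo.data)
        ]
        return "\n".join(lines) + "\n"


@dataclass
class SolverReport:
    """Diagnostics of one SPG-QP run."""

    objective_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    final_pg_norm: float = np.nan
    converged: bool = False
    iterates: list[NDArray[np.float64]] | None = None


def build_H(P: ArrayLike, K: int, T: int) -> sp.csr_matrix:
    """Hessian-like matrix of the Markov penalty, shape (K*T, K*T).

    ``(1/T) vec(Gamma)' H vec(Gamma)`` equals the Markov term
    ``(1/T) sum_t ||Gamma[:,t+1] - P Gamma[:,t]||^2`` for any K x K prior P
    (cluster-major vectorization).  With P = I, H is block diagonal with K
    copies of the T x T path-graph Laplacian.
    """
    if T < 2:
        raise ValueError("T >= 2 is required: a single time point has no transitions")
    P = np.asarray(P, dtype=float)
    if P.shape != (K, K):
        raise ValueError(f"P must be ({K}, {K}), got {P.shape}")
    d_late = sp.diags(np.r_[0.0, np.ones(T - 1)])  # t = 2..T
    d_early = sp.diags(np.r_[np.ones(T - 1), 0.0])  # t = 1..T-1
    od = sp.diags(-np.ones(T - 1), 1)  # superdiagonal -1
    H = (
        sp.kron(sp.identity(K), d_late)
        + sp.kron(P.T @ P, d_early)
        + sp.kron(P.T, od)
        + sp.kron(P, od.T)
    )
    return sp.csr_matrix(H)


def build_linear_term(
    X: ArrayLike,
    Pi: ArrayLike | None,
    theta: GaussianCentroids,
    lam: ArrayLike | None,
    W: ArrayLike,
    hp: HyperParams,
) -> NDArray[np.float64]:
    """Linear coefficients b of the Gamma-step QP, length K*T.

    ``B[k, t] = eps_L/T * sum_d W_d nll(X[d,t]; mu[d,k], sigma[d,k])
               - eps_CL/T * sum_m Pi[m,t] log Lambda[m,k]``,
    flattened cluster-major.  Signs are chosen so that
    ``b'g + (1/T) g'Hg`` equals the full objective up to the Gamma-independent
    entropy term.  In prediction mode (``Pi is None``) ``eps_CL`` must be 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    W = np.asarray(W, dtype=float).ravel()
    D, T = X.shape
    K = theta.K
    ell = nll_tensor(X, theta.mu, theta.sigma)  # (D, K, T)
    B = hp.eps_L / T * np.einsum("d,dkt->kt", W, ell)
    if hp.eps_CL > 0.0:
        if Pi is None or lam is None:
            raise ValueError("eps_CL > 0 requires Pi and Lambda")
        Pi = np.atleast_2d(np.asarray(Pi, dtype=float))
        lam = np.atleast_2d(np.asarray(lam, dtype=float))
        with np.errstate(divide="ignore"):
            log_lam = np.log(lam)
        log_lam[lam <= 0.0] = _LOG_ZERO_PENALTY
        B = B - hp.eps_CL / T * (log_lam.T @ Pi)  # (K, T)
    elif Pi is None and hp.eps_CL != 0.0:
        raise ValueError("prediction mode (Pi=None) requires eps_CL == 0")
    return B.ravel()


def project_simplex_columns(V: ArrayLike) -> NDArray[np.float64]:
    """Euclidean projection of each column onto the probability simplex.

    Sort-and-threshold algorithm, vectorized over columns; O(K log K) per
    column.  The projection is unique, so ties need no special handling.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    K = V.shape[0]
    if K == 1:
        return np.ones_like(V)
    U = np.sort(V, axis=0)[::-1]  # descending per column
    css = np.cumsum(U, axis=0) - 1.0
    idx = np.arange(1, K + 1)[:, None]
    cond = U - css / idx > 0.0
    rho = K - np.argmax(cond[::-1], axis=0) - 1  # last True per column
    tau = css[rho, np.arange(V.shape[1])] / (rho + 1.0)
    return np.maximum(V - tau, 0.0)


def spgqp_solve(
    qp: MarkovQP,
    gamma0: ArrayLike,
    tol: float | None = None,
    max_iter: int | None = None,
    keep_iterates: bool = False,
) -> tuple[NDArray[np.float64], SolverReport]:
    """Minimize the Gamma-step QP by spectral projected gradient.

    Parameters
    ----------
    qp : MarkovQP
        Problem data (H must be PSD for the convergence guarantee).
    gamma0 : array (K, T)
        Feasible starting affiliation (columns on the simplex).
    tol : float, optional
        Stopping threshold on the norm of the projected gradient step
        ``||proj(g - grad) - g||``; defaults to ``1e-10 * K * T`` (tight
        enough that independently started runs agree in the solution, not
        just the objective, whenever the minimizer is unique).
    max_iter : int, optional
        Iteration cap, default ``10 * K * T``.
    keep_iterates : bool
        Store every iterate in the report (tests only; memory-heavy).

    Returns
    -------
    (Gamma, report)
        ``Gamma`` is feasible with objective no worse than at ``gamma0``.
    """
    K, T = qp.K, qp.T
    if not np.isfinite(qp.b).all() or not np.isfinite(qp.H.data).all():
        raise ValueError("QP data contain non-finite entries")
    G0 = np.atleast_2d(np.asarray(gamma0, dtype=float))
    if G0.shape != (K, T):
        raise ValueError(f"gamma0 shaped {G0.shape}, expected ({K}, {T})")
    if not validate_feasible(G0, tol=1e-6):
        raise ValueError("gamma0 is not a feasible affiliation matrix")
    report = SolverReport(iterates=[] if keep_iterates else None)
    if K == 1:
        # constraint (column sums to one) pins Gamma to the all-ones row
        G = np.ones((1, T))
        report.objective_trace.append(qp.objective(G))
        report.final_pg_norm = 0.0
        report.converged = True
        return G, report

    if tol is None:
        tol = 1e-10 * K * T
    if max_iter is None:
        max_iter = 10 * K * T

    b = qp.b
    H = qp.H

    def matvec(v: NDArray[np.float64]) -> NDArray[np.float64]:
        return H @ v

    g = G0.ravel().copy()
    Hg = matvec(g)
    f = float(b @ g + g @ Hg / T)
    grad = b + 2.0 / T * Hg
    fbest, gbest = f, g.copy()
    report.objective_trace.append(f)
    if keep_iterates:
        report.iterates.append(g.reshape(K, T).copy())

    memory: deque[float] = deque([f], maxlen=10)
    alpha = 1.0
    alpha_min, alpha_max = 1e-10, 1e10

    def project_flat(v: NDArray[np.float64]) -> NDArray[np.float64]:
        return project_simplex_columns(v.reshape(K, T)).ravel()

    pg_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        pg = project_flat(g - grad) - g
        pg_norm = float(np.linalg.norm(pg))
        if pg_norm <= tol:
            report.converged = True
            break
        d = project_flat(g - alpha * grad) - g
        gd = float(grad @ d)
        if gd >= 0.0:
            # alpha too large for descent; shrink and retry next iteration
            alpha = max(alpha * 0.1, alpha_min)
            continue
        Hd = matvec(d)
        quad = float(d @ Hd) / T  # curvature along d; >= 0 for PSD H
        f_ref = max(memory)
        # nonmonotone Armijo on the exact quadratic f(g + lam*d)
        lam_step = 1.0
        for _ in range(60):
            f_new = f + lam_step * gd + lam_step * lam_step * quad
            if f_new <= f_ref + 1e-4 * lam_step * gd:
                break
            # minimizer of the 1-D quadratic, safeguarded halving
            lam_opt = -gd / (2.0 * quad) if quad > 0.0 else 0.5 * lam_step
            lam_step = min(0.5 * lam_step, max(lam_opt, 0.1 * lam_step))
        s = lam_step * d
        g = g + s
        y = 2.0 / T * Hd * lam_step  # = grad(g+s) - grad(g)
        grad = grad + y
        f = f + lam_step * gd + lam_step * lam_step * quad
        memory.append(f)
        if f < fbest:
            fbest, gbest = f, g.copy()
        report.objective_trace.append(f)
        if keep_iterates:
            report.iterates.append(g.reshape(K, T).copy())
        sy = float(s @ y)
        if sy > 0.0:
            alpha = float(np.clip(float(s @ s) / sy, alpha_min, alpha_max))
        else:
            alpha = alpha_max

    report.iterations = it
    report.final_pg_norm = pg_norm
    G = gbest.reshape(K, T)
    # numerical cleanup: projection is idempotent on the feasible set
    G = project_simplex_columns(G)
    return G, report
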