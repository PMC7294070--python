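"""Sparse-representation network estimators and their proximal solvers.

Each estimator regresses every ROI's signal on all other ROIs' signals
(columns of the subject's data matrix), so the learned coefficients act
as regularized partial correlations.  Writing ``X`` for the (column
standardized) ``T x N`` data matrix and ``W`` for the ``N x N``
coefficient matrix with a structurally zero diagonal, the family is:

* **SR**    ``min 1/2 ||X - XW||_F^2 + lam ||W||_1``
* **WSR**   ``... + lam1 ||C o W||_1`` with link weights
  ``C_ij = exp(-FC_ij^2 / sigma)`` from the same subject's PC network —
  strong PC links are penalized less.
* **WSGR**  WSR plus a sparse-group term ``lam2 * sum_g d_g ||W_{O_g}||_2``
  over G strength bins of edges, ``d_g = exp(-E_g^2 / sigma)``.
* **GSR**   per-ROI multi-subject joint estimation with an l2,1 penalty
  across subjects (common support).
* **SSGSR** GSR with per-entry weights ``B`` and a graph-Laplacian term
  ``lam2 * tr(W_i L_i W_i')`` pulling similar subjects' coefficients
  together.
* **SLR**   ``min ||X - XW||_F^2 + lam1 ||W||_1 + lam2 ||W||_*``
  (note: no 1/2 on the loss), solved by ADMM; the nuclear norm promotes
  low rank / modular structure.

All single-subject problems decouple by column and are solved with
FISTA at the exact Lipschitz step; SLR uses ADMM with soft-thresholding
and singular-value thresholding.  Every returned network is symmetrized
``W <- (W + W')/2``; solvers attach a convergence certificate (final
objective, iterations, prox-gradient/ADMM residual).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .data import ConnectivityMatrix, Dataset, symmetrize
from .pairwise import pair_index, pearson_network

__all__ = [
    "SolverConfig",
    "Certificate",
    "soft_threshold",
    "group_soft_threshold",
    "svd_soft_threshold",
    "normalize_signals",
    "estimate_sigma",
    "link_penalty_weights",
    "group_edges",
    "EdgeGrouping",
    "ssgsr_weights",
    "subject_similarity_laplacians",
    "sr_network",
    "wsr_network",
    "wsgr_network",
    "gsr_networks",
    "ssgsr_networks",
    "slr_network",
    "sr_lambda_max",
    "gsr_lambda_max",
]


@dataclass
class SolverConfig:
    """Iteration control shared by all solvers."""

    tol: float = 1e-6  # relative objective-change tolerance
    kkt_tol: float = 1e-6  # prox-gradient fixed-point residual target
    max_iter: int = 2000
    admm_rho: float = 1.0


@dataclass
class Certificate:
    """Convergence certificate attached to every solve."""

    objective: float
    n_iter: int
    kkt_residual: float
    converged: bool


# ---------------------------------------------------------------------------
# Prox kernels
# ---------------------------------------------------------------------------


def soft_threshold(v, t):
    """Elementwise ``sign(v) * max(|v| - t, 0)``; ``t`` may be an array."""
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def group_soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    """Block shrinkage: scales ``v`` by ``max(1 - t/||v||_2, 0)``."""
    nrm = np.linalg.norm(v)
    if nrm <= t:
        return np.zeros_like(v)
    return (1.0 - t / nrm) * v


def svd_soft_threshold(A: np.ndarray, t: float) -> np.ndarray:
    """Singular-value soft-thresholding (prox of ``t * ||.||_*``)."""
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    s = np.maximum(s - t, 0.0)
    return (U * s) @ Vt


def _weighted_group_prox(z: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Prox of ``t * ||b o v||_2`` (entrywise positive weights ``b``).

    The minimizer of ``1/2 ||u - z||^2 + t ||diag(b) u||_2`` is 0 iff
    ``||z / b||_2 <= t``; otherwise ``u_k = z_k / (1 + t b_k^2 / r)``
    where ``r = ||diag(b) u||_2`` solves a scalar fixed-point equation
    (found by bracketed root-finding).
    """
    if t <= 0:
        return z.copy()
    if np.linalg.norm(z / b) <= t:
        return np.zeros_like(z)
    b2 = b * b

    def h(r):
        u = z / (1.0 + t * b2 / r)
        return np.linalg.norm(b * u) - r

    hi = np.linalg.norm(b * z)
    r = brentq(h, 1e-14 * max(hi, 1.0), hi, xtol=1e-15, rtol=1e-15)
    return z / (1.0 + t * b2 / r)


# ---------------------------------------------------------------------------
# Standardization and penalty preparation
# ---------------------------------------------------------------------------


def normalize_signals(X: np.ndarray) -> np.ndarray:
    """Standardize each column to zero mean and unit l2 norm.

    Idempotent; leaves the correlation structure unchanged.  Raises on a
    constant column (callers are expected to have screened those).
    """
    X = np.asarray(X, dtype=float)
    Z = X - X.mean(axis=0)
    nrm = np.linalg.norm(Z, axis=0)
    if np.any(nrm == 0):
        raise ValueError(
            f"constant column(s) {np.where(nrm == 0)[0].tolist()} cannot be normalized"
        )
    return Z / nrm


def estimate_sigma(pc_networks: list[ConnectivityMatrix | np.ndarray]) -> float:
    """Penalty decay scale: per subject, the standard deviation of the
    off-diagonal |PC| strengths; sigma is the mean of these over subjects."""
    stds = []
    for W in pc_networks:
        V = W.values if isinstance(W, ConnectivityMatrix) else np.asarray(W, float)
        iu = np.triu_indices(V.shape[0], k=1)
        offdiag = np.abs(np.concatenate([V[iu], V.T[iu]]))
        stds.append(offdiag.std())
    sigma = float(np.mean(stds))
    if sigma <= 0:
        raise ValueError("degenerate sigma (identical |PC| everywhere)")
    return sigma


def link_penalty_weights(W_pc: ConnectivityMatrix | np.ndarray, sigma: float) -> np.ndarray:
    """WSR/WSGR link weights ``C_ij = exp(-FC_ij^2 / sigma)``."""
    V = W_pc.values if isinstance(W_pc, ConnectivityMatrix) else np.asarray(W_pc, float)
    return np.exp(-(V**2) / sigma)


@dataclass
class EdgeGrouping:
    """Partition of the off-diagonal edges into G strength bins."""

    G: int
    membership: np.ndarray  # length P, values in 0..G-1 (edge order: pair_index)
    E: np.ndarray  # group-mean absolute PC strength per bin
    pairs: list[tuple[int, int]] = field(default_factory=list)

    def group_of_edge(self) -> dict[tuple[int, int], int]:
        return {p: int(g) for p, g in zip(self.pairs, self.membership)}


def group_edges(pc_networks: list[ConnectivityMatrix | np.ndarray], G: int = 10) -> EdgeGrouping:
    """Group edges into ``G`` equal-frequency (quantile) bins of their
    cohort-mean absolute PC strength.  Deterministic; bins with no
    distinct boundary collapse (warning)."""
    if G < 2:
        raise ValueError("need at least 2 groups")
    mats = [
        W.values if isinstance(W, ConnectivityMatrix) else np.asarray(W, float)
        for W in pc_networks
    ]
    N = mats[0].shape[0]
    iu = np.triu_indices(N, k=1)
    strength = np.mean([np.abs(V)[iu] for V in mats], axis=0)  # per edge
    P = strength.size
    if G > P:
        raise ValueError(f"G={G} exceeds number of edges P={P}")
    qs = np.quantile(strength, np.linspace(0, 1, G + 1)[1:-1])
    membership = np.searchsorted(qs, strength, side="left")
    present = np.unique(membership)
    if present.size < G:
        warnings.warn(
            f"only {present.size} of {G} strength bins are distinct; bins merged",
            stacklevel=2,
        )
        remap = {g: k for k, g in enumerate(present)}
        membership = np.array([remap[g] for g in membership])
        G = present.size
    E = np.array([strength[membership == g].mean() for g in range(G)])
    return EdgeGrouping(G=G, membership=membership, E=E, pairs=pair_index(N))


def group_weights(E: np.ndarray, sigma: float) -> np.ndarray:
    """WSGR group weights ``d_g = exp(-E_g^2 / sigma)``."""
    return np.exp(-(np.asarray(E, float) ** 2) / sigma)


def ssgsr_weights(pc_networks: list[ConnectivityMatrix | np.ndarray]) -> np.ndarray:
    """SSGSR penalty weights ``b_{i,j}^m = exp(-(w_{i,j}^m)^2)``.

    Returns an array of shape (N, N-1, M): for ROI i, row j (candidate
    connection, own index removed), subject m.  Weak PC links get
    weights near 1 (penalized more), strong links near exp(-1).
    """
    mats = [
        W.values if isinstance(W, ConnectivityMatrix) else np.asarray(W, float)
        for W in pc_networks
    ]
    N = mats[0].shape[0]
    M = len(mats)
    B = np.empty((N, N - 1, M))
    for i in range(N):
        keep = [j for j in range(N) if j != i]
        for m, V in enumerate(mats):
            B[i, :, m] = np.exp(-(V[i, keep] ** 2))
    return B


def subject_similarity_laplacians(
    pc_networks: list[ConnectivityMatrix | np.ndarray],
) -> np.ndarray:
    """Per-ROI subject-similarity graph Laplacians.

    For ROI i, ``S_i[m, l] = exp(-||w_i.^m - w_i.^l||^2)`` over the PC
    profiles (own entry removed) and ``L_i = D_i - S_i``.  Returned as an
    array (N, M, M); each Laplacian is symmetric PSD with zero row sums.
    """
    mats = [
        W.values if isinstance(W, ConnectivityMatrix) else np.asarray(W, float)
        for W in pc_networks
    ]
    N = mats[0].shape[0]
    M = len(mats)
    L = np.empty((N, M, M))
    for i in range(N):
        keep = [j for j in range(N) if j != i]
        prof = np.stack([V[i, keep] for V in mats])  # M x (N-1)
        d2 = ((prof[:, None, :] - prof[None, :, :]) ** 2).sum(axis=2)
        S = np.exp(-d2)
        L[i] = np.diag(S.sum(axis=1)) - S
    return L


# ---------------------------------------------------------------------------
# FISTA engine
# ---------------------------------------------------------------------------


def _fista(grad, prox, objective, x0, step, cfg: SolverConfig):
    """FISTA with fixed step (exact Lipschitz constant) and adaptive
    (function-value) restart.  Convergence is declared when the
    prox-gradient fixed-point residual ``max|x - prox(x - step*grad(x))|
    / step`` drops below ``cfg.kkt_tol`` or the relative objective change
    below ``cfg.tol`` with residual already below 10x the target."""
    x = x0.copy()
    y = x0.copy()
    t = 1.0
    f_prev = objective(x)
    resid = np.inf
    for it in range(1, cfg.max_iter + 1):
        x_new = prox(y - step * grad(y), step)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        f_new = objective(x_new)
        if f_new > f_prev:  # restart momentum
            y = x.copy()
            t = 1.0
            x_new = prox(y - step * grad(y), step)
            f_new = objective(x_new)
            t_new = 1.0
        y = x_new + ((t - 1.0) / t_new) * (x_new - x)
        x, t = x_new, t_new
        resid = float(np.max(np.abs(x - prox(x - step * grad(x), step))) / step)
        if resid <= cfg.kkt_tol:
            f_prev = f_new
            break
        f_prev = f_new
    else:
        it = cfg.max_iter
    cert = Certificate(
        objective=float(objective(x)),
        n_iter=it,
        kkt_residual=resid,
        converged=resid <= 10 * cfg.kkt_tol,
    )
    if not cert.converged:
        warnings.warn(
            f"solver stopped at max_iter={cfg.max_iter} with residual {resid:.2e}",
            stacklevel=3,
        )
    return x, cert


def _spectral_step(D: np.ndarray) -> float:
    """1 / L with L = ||D'D||_2, the exact Lipschitz constant of the
    quadratic loss."""
    s = np.linalg.norm(D, 2)
    return 1.0 / max(s * s, 1e-12)


# ---------------------------------------------------------------------------
# Single-subject solvers (columnwise)
# ---------------------------------------------------------------------------


def _columnwise_solve(X, make_prox, cfg, lam_desc):
    """Shared driver: for each ROI i regress x_i on X_{-i} with the
    penalty encoded by ``make_prox(i)``; assemble W with zero diagonal."""
    T, N = X.shape
    W = np.zeros((N, N))
    certs = []
    for i in range(N):
        keep = [j for j in range(N) if j != i]
        D = X[:, keep]
        x = X[:, i]
        step = _spectral_step(D)
        DtD = D.T @ D
        Dtx = D.T @ x

        def grad(w):
            return DtD @ w - Dtx

        def obj(w):
            r = x - D @ w
            return 0.5 * float(r @ r) + lam_desc(i, w)

        prox = make_prox(i)
        w, cert = _fista(grad, prox, obj, np.zeros(N - 1), step, cfg)
        W[keep, i] = w
        certs.append(cert)
    return W, certs


def _finalize(W, method, params, certs, symmetrize_out):
    pre = W.copy()
    V = symmetrize(W) if symmetrize_out else W
    cm = ConnectivityMatrix(V, method=method, params=params)
    cm.extras["certificates"] = certs
    cm.extras["pre_symmetrization"] = pre
    return cm


def sr_network(
    X: np.ndarray,
    lam: float,
    cfg: SolverConfig | None = None,
    normalize: bool = True,
    symmetrize_out: bool = True,
) -> ConnectivityMatrix:
    """Sparse representation (columnwise lasso partial correlation)."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    cfg = cfg or SolverConfig()
    X = normalize_signals(X) if normalize else np.asarray(X, dtype=float)

    def make_prox(i):
        return lambda z, step: soft_threshold(z, step * lam)

    W, certs = _columnwise_solve(
        X, make_prox, cfg, lambda i, w: lam * np.abs(w).sum()
    )
    return _finalize(W, "SR", {"lambda": lam}, certs, symmetrize_out)


def sr_lambda_max(X: np.ndarray, normalize: bool = True) -> float:
    """Smallest lambda at which the SR solution is exactly zero:
    ``max_i ||X_{-i}' x_i||_inf``."""
    X = normalize_signals(X) if normalize else np.asarray(X, dtype=float)
    N = X.shape[1]
    G = np.abs(X.T @ X - np.diag(np.diag(X.T @ X)))
    return float(G.max())


def wsr_network(
    X: np.ndarray,
    lam1: float,
    C: np.ndarray,
    cfg: SolverConfig | None = None,
    normalize: bool = True,
    symmetrize_out: bool = True,
) -> ConnectivityMatrix:
    """Weighted SR: link (i, j) is thresholded at ``lam1 * C_ij``."""
    if lam1 <= 0:
        raise ValueError("lambda1 must be positive")
    cfg = cfg or SolverConfig()
    X = normalize_signals(X) if normalize else np.asarray(X, dtype=float)
    C = np.asarray(C, dtype=float)
    N = X.shape[1]
    if C.shape != (N, N):
        raise ValueError("penalty weight matrix C must be N x N")

    def col_weights(i):
        keep = [j for j in range(N) if j != i]
        return C[keep, i]

    def make_prox(i):
        c = col_weights(i)
        return lambda z, step: soft_threshold(z, step * lam1 * c)

    W, certs = _columnwise_solve(
        X, make_prox, cfg, lambda i, w: lam1 * float(np.abs(col_weights(i) * w).sum())
    )
    return _finalize(W, "WSR", {"lambda1": lam1}, certs, symmetrize_out)


def wsgr_network(
    X: np.ndarray,
    lam1: float,
    lam2: float,
    C: np.ndarray,
    grouping: EdgeGrouping,
    d: np.ndarray,
    cfg: SolverConfig | None = None,
    normalize: bool = True,
    symmetrize_out: bool = True,
) -> ConnectivityMatrix:
    """Strength-weighted sparse group representation.

    The prox of the sum of an elementwise l1 term and a group-l2 term is
    the composition: soft-threshold first, then group shrinkage per bin.
    """
    if lam1 < 0 or lam2 < 0 or (lam1 == 0 and lam2 == 0):
        raise ValueError("lambda1/lambda2 must be nonnegative, not both zero")
    cfg = cfg or SolverConfig()
    X = normalize_signals(X) if normalize else np.asarray(X, dtype=float)
    C = np.asarray(C, dtype=float)
    d = np.asarray(d, dtype=float)
    N = X.shape[1]
    edge_group = grouping.group_of_edge()

    def col_structure(i):
        keep = [j for j in range(N) if j != i]
        c = C[keep, i]
        groups = np.array(
            [edge_group[(min(i, j), max(i, j))] for j in keep], dtype=int
        )
        return c, groups

    def make_prox(i):
        c, groups = col_structure(i)
        idx_by_g = [np.where(groups == g)[0] for g in range(grouping.G)]

        def prox(z, step):
            u = soft_threshold(z, step * lam1 * c)
            for g, idx in enumerate(idx_by_g):
                if idx.size:
                    u[idx] = group_soft_threshold(u[idx], step * lam2 * d[g])
            return u

        return prox

    def penalty(i, w):
        c, groups = col_structure(i)
        val = lam1 * float(np.abs(c * w).sum())
        for g in range(grouping.G):
            idx = np.where(groups == g)[0]
            if idx.size:
                val += lam2 * d[g] * float(np.linalg.norm(w[idx]))
        return val

    W, certs = _columnwise_solve(X, make_prox, cfg, penalty)
    return _finalize(
        W, "WSGR", {"lambda1": lam1, "lambda2": lam2, "G": grouping.G}, certs, symmetrize_out
    )


# ---------------------------------------------------------------------------
# Multi-subject (group) solvers
# ---------------------------------------------------------------------------


def _group_solve(Xs, lam1, lam2, B, laplacians, cfg, method, symmetrize_out):
    """Shared GSR/SSGSR driver.  For each ROI i the unknown is a
    (N-1) x M matrix V (rows: candidate connections, columns: subjects)
    minimizing

        sum_m 1/2 ||x_i^m - X_{-i}^m v_m||^2
        + lam1 * sum_j ||(B_i)_j. o V_j.||_2          (l2,1, weighted)
        + lam2 * tr(V L_i V')                          (SSGSR only)
    """
    M = len(Xs)
    N = Xs[0].shape[1]
    Ws = [np.zeros((N, N)) for _ in range(M)]
    certs = []
    for i in range(N):
        keep = [j for j in range(N) if j != i]
        Ds = [X[:, keep] for X in Xs]
        xs = [X[:, i] for X in Xs]
        DtD = [D.T @ D for D in Ds]
        Dtx = [D.T @ x for D, x in zip(Ds, xs)]
        L_i = None if laplacians is None else laplacians[i]
        lip = max(np.linalg.norm(D, 2) ** 2 for D in Ds)
        if L_i is not None and lam2 > 0:
            lip += 2.0 * lam2 * np.linalg.norm(L_i, 2)
        step = 1.0 / max(lip, 1e-12)
        B_i = None if B is None else np.asarray(B[i], dtype=float)

        def grad(V):
            G = np.column_stack([DtD[m] @ V[:, m] - Dtx[m] for m in range(M)])
            if L_i is not None and lam2 > 0:
                G = G + 2.0 * lam2 * V @ L_i
            return G

        # the Laplacian term is smooth (handled in grad); the prox only
        # sees the (weighted) l2,1 term
        def obj(V):
            val = 0.0
            for m in range(M):
                r = xs[m] - Ds[m] @ V[:, m]
                val += 0.5 * float(r @ r)
            if B_i is None:
                val += lam1 * float(np.linalg.norm(V, axis=1).sum())
            else:
                val += lam1 * float(np.linalg.norm(B_i * V, axis=1).sum())
            if L_i is not None and lam2 > 0:
                val += lam2 * float(np.trace(V @ L_i @ V.T))
            return val

        if B_i is None:

            def prox(Z, step):
                U = Z.copy()
                for j in range(U.shape[0]):
                    U[j] = group_soft_threshold(U[j], step * lam1)
                return U

        else:

            def prox(Z, step):
                U = Z.copy()
                for j in range(U.shape[0]):
                    U[j] = _weighted_group_prox(Z[j], B_i[j], step * lam1)
                return U

        V0 = np.zeros((N - 1, M))
        V, cert = _fista(grad, prox, obj, V0, step, cfg)
        for m in range(M):
            Ws[m][keep, i] = V[:, m]
        certs.append(cert)
    out = []
    params = {"lambda": lam1} if method == "GSR" else {"lambda1": lam1, "lambda2": lam2}
    for m in range(M):
        out.append(_finalize(Ws[m], method, dict(params), certs, symmetrize_out))
    return out


def gsr_networks(
    Xs: list[np.ndarray],
    lam: float,
    cfg: SolverConfig | None = None,
    normalize: bool = True,
    symmetrize_out: bool = True,
) -> list[ConnectivityMatrix]:
    """Group SR: joint estimation across subjects with an l2,1 penalty
    (identical support across subjects).  Labels are never an input."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    cfg = cfg or SolverConfig()
    Xs = [normalize_signals(X) if normalize else np.asarray(X, float) for X in Xs]
    ns = {X.shape[1] for X in Xs}
    if len(ns) > 1:
        raise ValueError("all subjects must share N")
    return _group_solve(Xs, lam, 0.0, None, None, cfg, "GSR", symmetrize_out)


def gsr_lambda_max(Xs: list[np.ndarray], normalize: bool = True) -> float:
    """Smallest lambda making the GSR solution exactly zero:
    ``max_{i,j} || (X_{-i}^m ' x_i^m)_j stacked over m ||_2``."""
    Xs = [normalize_signals(X) if normalize else np.asarray(X, float) for X in Xs]
    N = Xs[0].shape[1]
    worst = 0.0
    for i in range(N):
        keep = [j for j in range(N) if j != i]
        R = np.column_stack([X[:, keep].T @ X[:, i] for X in Xs])  # (N-1) x M
        worst = max(worst, float(np.linalg.norm(R, axis=1).max()))
    return worst


def ssgsr_networks(
    Xs: list[np.ndarray],
    lam1: float,
    lam2: float,
    B: np.ndarray | None = None,
    laplacians: np.ndarray | None = None,
    cfg: SolverConfig | None = None,
    normalize: bool = True,
    symmetrize_out: bool = True,
) -> list[ConnectivityMatrix]:
    """Strength- and similarity-guided GSR.

    ``B`` and the per-ROI Laplacians default to the values derived from
    the cohort's PC networks (label-free).  A numerically non-PSD
    Laplacian is symmetrized and its negative eigenvalues clipped at 0
    with a warning.
    """
    if lam1 <= 0 or lam2 < 0:
        raise ValueError("lambda1 must be positive, lambda2 nonnegative")
    cfg = cfg or SolverConfig()
    Xn = [normalize_signals(X) if normalize else np.asarray(X, float) for X in Xs]
    if B is None or laplacians is None:
        pcs = [pearson_network(X) for X in Xs]
        if B is None:
            B = ssgsr_weights(pcs)
        if laplacians is None:
            laplacians = subject_similarity_laplacians(pcs)
    laps = []
    for L_i in np.asarray(laplacians, dtype=float):
        Ls = (L_i + L_i.T) / 2.0
        evals, evecs = np.linalg.eigh(Ls)
        if evals.min() < -1e-10:
            warnings.warn("Laplacian not PSD; clipping negative eigenvalues", stacklevel=2)
            Ls = (evecs * np.maximum(evals, 0.0)) @ evecs.T
        laps.append(Ls)
    return _group_solve(Xn, lam1, lam2, B, laps, cfg, "SSGSR", symmetrize_out)


# ---------------------------------------------------------------------------
# Sparse low-rank (ADMM)
# ---------------------------------------------------------------------------


def slr_network(
    X: np.ndarray,
    lam1: float,
    lam2: float,
    cfg: SolverConfig | None = None,
    normalize: bool = True,
    symmetrize_out: bool = True,
) -> ConnectivityMatrix:
    """Sparse low-rank graph learning.

    Minimizes ``||X - XW||_F^2 + lam1 ||W||_1 + lam2 ||W||_*`` (loss
    without the 1/2 factor) over W with zero diagonal, by ADMM with two
    splitting variables: Z1 carries the l1 term + diagonal constraint,
    Z2 the nuclear norm.  The returned matrix is Z1 at convergence
    (exact zeros, exact zero diagonal), then symmetrized.
    """
    if lam1 < 0 or lam2 < 0 or (lam1 == 0 and lam2 == 0):
        raise ValueError("lambda1/lambda2 must be nonnegative, not both zero")
    cfg = cfg or SolverConfig()
    X = normalize_signals(X) if normalize else np.asarray(X, dtype=float)
    N = X.shape[1]
    rho = cfg.admm_rho
    G = X.T @ X
    evals, Q = np.linalg.eigh(G)
    inv = 1.0 / (2.0 * evals + 2.0 * rho)
    RHS0 = 2.0 * G
    Z1 = np.zeros((N, N))
    Z2 = np.zeros((N, N))
    U1 = np.zeros((N, N))
    U2 = np.zeros((N, N))
    r_p = r_d = np.inf
    it = 0
    for it in range(1, cfg.max_iter + 1):
        RHS = RHS0 + rho * (Z1 - U1 + Z2 - U2)
        W = Q @ ((Q.T @ RHS) * inv[:, None])
        Z1_new = soft_threshold(W + U1, lam1 / rho)
        np.fill_diagonal(Z1_new, 0.0)
        Z2_new = svd_soft_threshold(W + U2, lam2 / rho)
        r_d = rho * max(
            np.max(np.abs(Z1_new - Z1)), np.max(np.abs(Z2_new - Z2))
        )
        Z1, Z2 = Z1_new, Z2_new
        U1 = U1 + W - Z1
        U2 = U2 + W - Z2
        r_p = max(np.max(np.abs(W - Z1)), np.max(np.abs(W - Z2)))
        if r_p <= 1e-6 and r_d <= 1e-6:
            break
    resid = max(r_p, r_d)

    def objective(V):
        R = X - X @ V
        return (
            float((R * R).sum())
            + lam1 * float(np.abs(V).sum())
            + lam2 * float(np.linalg.svd(V, compute_uv=False).sum())
        )

    cert = Certificate(
        objective=objective(Z1),
        n_iter=it,
        kkt_residual=float(resid),
        converged=resid <= 1e-5,
    )
    if not cert.converged:
        warnings.warn(
            f"ADMM stopped at iteration {it} with residual {resid:.2e}", stacklevel=2
        )
    pre = Z1.copy()
    V = symmetrize(Z1) if symmetrize_out else Z1
    cm = ConnectivityMatrix(V, method="SLR", params={"lambda1": lam1, "lambda2": lam2})
    cm.extras["certificates"] = [cert]
    cm.extras["pre_symmetrization"] = pre
    return cm


# ---------------------------------------------------------------------------
# Cohort-level convenience: construct networks for a Dataset
# ---------------------------------------------------------------------------


def construct_sparse_networks(
    dataset: Dataset,
    method: str,
    params: dict,
    cfg: SolverConfig | None = None,
    subset: list[int] | None = None,
) -> list[ConnectivityMatrix]:
    """Dispatch a sparse method over a cohort.

    Per-subject methods (SR, WSR, WSGR, SLR) solve independently; group
    methods (GSR, SSGSR) solve jointly over the given subjects.  Penalty
    weights (sigma, C, groups, B, Laplacians) are derived from PC
    networks of the involved subjects — labels are never consulted.
    """
    cfg = cfg or SolverConfig()
    idx = list(range(dataset.n_subjects)) if subset is None else list(subset)
    Xs = [dataset.subjects[i].data for i in idx]
    if method == "SR":
        return [sr_network(X, params["lambda"], cfg) for X in Xs]
    if method == "SLR":
        return [slr_network(X, params["lambda1"], params["lambda2"], cfg) for X in Xs]
    pcs = [pearson_network(X) for X in Xs]
    sigma = estimate_sigma(pcs)
    if method == "WSR":
        return [
            wsr_network(X, params["lambda1"], link_penalty_weights(pc, sigma), cfg)
            for X, pc in zip(Xs, pcs)
        ]
    if method == "WSGR":
        grouping = group_edges(pcs, G=int(params.get("G", 10)))
        d = group_weights(grouping.E, sigma)
        return [
            wsgr_network(
                X,
                params["lambda1"],
                params["lambda2"],
                link_penalty_weights(pc, sigma),
                grouping,
                d,
                cfg,
            )
            for X, pc in zip(Xs, pcs)
        ]
    if method == "GSR":
        return gsr_networks(Xs, params["lambda"], cfg)
    if method == "SSGSR":
        return ssgsr_networks(
            Xs,
            params["lambda1"],
            params["lambda2"],
            B=ssgsr_weights(pcs),
            laplacians=subject_similarity_laplacians(pcs),
            cfg=cfg,
        )
    raise ValueError(f"not a sparse method: {method!r}")
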