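"""Independent brute-force / slow reference implementations used only to
check the package's fast paths.  Everything here is written from the
defining formulas with explicit loops or generic optimizers, sharing no
code with the package."""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


# ---------------------------------------------------------------------------
# Correlation-based constructors, straight from the defining sums
# ---------------------------------------------------------------------------


def corr_pair(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    den = np.sqrt((am**2).sum() * (bm**2).sum())
    if den == 0:
        return 0.0
    return float((am * bm).sum() / den)


def bf_pearson(X):
    T, N = X.shape
    W = np.eye(N)
    for i in range(N):
        for j in range(N):
            if i != j:
                W[i, j] = corr_pair(X[:, i], X[:, j])
    return W


def bf_thofc(W):
    N = W.shape[0]
    H = np.eye(N)
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            ks = [k for k in range(N) if k != i and k != j]
            H[i, j] = corr_pair([W[i, k] for k in ks], [W[j, k] for k in ks])
    return H


def bf_ahofc(H, W, symmetrized=True):
    N = W.shape[0]
    A = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            ks = [k for k in range(N) if k != i and k != j]
            A[i, j] = corr_pair([H[i, k] for k in ks], [W[j, k] for k in ks])
    if symmetrized:
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
    return A


def bf_dhofc(series):
    """series: Theta x K cluster-mean dynamic FC matrix."""
    K = series.shape[1]
    D = np.eye(K)
    for p in range(K):
        for q in range(K):
            if p != q:
                D[p, q] = corr_pair(series[:, p], series[:, q])
    return D


def bf_weighted_clustering(W):
    """Weighted local clustering coefficient: max-normalized |weights|,
    cube-root triple products over k(k-1)."""
    A = np.abs(np.asarray(W, float)).copy()
    np.fill_diagonal(A, 0.0)
    if A.max() > 0:
        A = A / A.max()
    N = A.shape[0]
    c = np.zeros(N)
    for u in range(N):
        k = int((A[u] > 0).sum())
        if k < 2:
            continue
        s = 0.0
        for v in range(N):
            for w in range(N):
                if v != u and w != u and v != w:
                    s += (A[u, v] * A[u, w] * A[v, w]) ** (1.0 / 3.0)
        c[u] = s / (k * (k - 1))
    return c


# ---------------------------------------------------------------------------
# Slow solvers
# ---------------------------------------------------------------------------


def cd_lasso(D, x, lam, n_iter=20000, tol=1e-14):
    """Coordinate descent for min 1/2||x - Dw||^2 + lam ||w||_1."""
    D = np.asarray(D, float)
    x = np.asarray(x, float)
    p = D.shape[1]
    w = np.zeros(p)
    col_sq = (D**2).sum(axis=0)
    r = x.copy()
    for _ in range(n_iter):
        delta = 0.0
        for j in range(p):
            if col_sq[j] == 0:
                continue
            rho = D[:, j] @ r + col_sq[j] * w[j]
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / col_sq[j]
            if new != w[j]:
                r += D[:, j] * (w[j] - new)
                delta = max(delta, abs(new - w[j]))
                w[j] = new
        if delta < tol:
            break
    return w


def ista_group_lasso(D, x, lam, n_iter=200000, groups=None):
    """Plain ISTA for min 1/2||x - Dw||^2 + lam * sum_g ||w_g||_2."""
    D = np.asarray(D, float)
    x = np.asarray(x, float)
    p = D.shape[1]
    if groups is None:
        groups = [np.arange(p)]
    step = 1.0 / np.linalg.norm(D, 2) ** 2
    w = np.zeros(p)
    for _ in range(n_iter):
        g = D.T @ (D @ w - x)
        z = w - step * g
        new = z.copy()
        for idx in groups:
            nrm = np.linalg.norm(z[idx])
            new[idx] = 0.0 if nrm <= step * lam else (1 - step * lam / nrm) * z[idx]
        if np.max(np.abs(new - w)) < 1e-14:
            w = new
            break
        w = new
    return w


def subgradient_ssgsr(Ds, xs, lam1, lam2, B_rows, L, n_iter=100000):
    """Projected subgradient descent (diminishing step) for the per-ROI
    SSGSR objective; returns the best objective value seen.

    Ds: list of M dictionaries (T x p); xs: list of M targets; B_rows:
    p x M weights; L: M x M Laplacian.
    """
    M = len(Ds)
    p = Ds[0].shape[1]
    V = np.zeros((p, M))

    def obj(V):
        val = 0.0
        for m in range(M):
            r = xs[m] - Ds[m] @ V[:, m]
            val += 0.5 * float(r @ r)
        val += lam1 * float(np.linalg.norm(B_rows * V, axis=1).sum())
        val += lam2 * float(np.trace(V @ L @ V.T))
        return val

    best = obj(V)
    best_V = V.copy()
    lip = max(np.linalg.norm(D, 2) ** 2 for D in Ds) + 2 * lam2 * np.linalg.norm(L, 2)
    base = 1.0 / lip
    for t in range(1, n_iter + 1):
        G = np.column_stack([Ds[m].T @ (Ds[m] @ V[:, m] - xs[m]) for m in range(M)])
        G += 2 * lam2 * V @ L
        BV = B_rows * V
        nrm = np.linalg.norm(BV, axis=1, keepdims=True)
        sub = np.where(nrm > 0, B_rows * BV / np.maximum(nrm, 1e-300), 0.0)
        G += lam1 * sub
        V = V - base / np.sqrt(t) * G
        f = obj(V)
        if f < best:
            best = f
            best_V = V.copy()
    return best, best_V


def svm_dual_qp(F, y, C):
    """Soft-margin linear SVM via its dual QP, solved with SLSQP:
    max sum(a) - 1/2 a' Q a  s.t. 0 <= a <= C, y'a = 0."""
    F = np.asarray(F, float)
    y = np.asarray(y, float)
    n = len(y)
    Q = (y[:, None] * F) @ (y[:, None] * F).T

    def neg_dual(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - 1.0

    cons = [{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}]
    bounds = [(0.0, C)] * n
    res = minimize(
        neg_dual, np.full(n, min(C, 1.0) / 2), jac=grad, bounds=bounds,
        constraints=cons, method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    a = res.x
    w = ((a * y)[:, None] * F).sum(axis=0)
    sv = (a > 1e-8) & (a < C - 1e-8)
    if sv.any():
        b = float(np.mean(y[sv] - F[sv] @ w))
    else:
        lo = -np.inf
        hi = np.inf
        for i in range(n):
            v = y[i] - F[i] @ w
            if (y[i] == 1 and a[i] < C - 1e-8) or (y[i] == -1 and a[i] > 1e-8):
                hi = min(hi, v) if y[i] == 1 else hi
            lo = max(lo, v) if (y[i] == 1 and a[i] > C - 1e-8) else lo
        b = float(np.clip(0.0, lo, hi)) if np.isfinite(lo) or np.isfinite(hi) else 0.0
    return w, b, a
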