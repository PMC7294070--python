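"""Feature extraction from networks and training-fold-only selection.

Networks become feature vectors either as raw edge weights (upper
triangle, ``(i, j)`` with ``i < j``, lexicographic) or as weighted local
clustering coefficients (one per node, computed on ``|W|`` after
max-normalizing the weights, with cube-root triple products — the
standard weighted generalization).

Selection operates strictly on training data: a two-sample pooled
variance t-test (keep ``p < alpha``), an l1-penalized regression of the
+-1 labels on standardized features (keep nonzero coefficients), or the
composition t-test-then-LASSO.  The returned :class:`SelectionResult`
carries the selected original column indices *and* the training-fold
standardization so the identical transform is applied to test subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import Lasso

from .data import ConnectivityMatrix

__all__ = [
    "FeatureMatrix",
    "SelectionResult",
    "vectorize_edges",
    "unvectorize_edges",
    "clustering_coefficients",
    "features_from_networks",
    "ttest_select",
    "lasso_select",
    "select_features",
]


@dataclass
class FeatureMatrix:
    """M x d feature values with a map from columns back to edges/nodes."""

    values: np.ndarray
    index_map: list  # column -> (i, j) edge or node/cluster id
    feature_type: str  # "edge_weights" | "clustering_coeff"

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def vectorize_edges(W: ConnectivityMatrix | np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Upper triangle (excluding diagonal) of a symmetric matrix, in
    (i < j) lexicographic order."""
    V = W.values if isinstance(W, ConnectivityMatrix) else np.asarray(W, float)
    if np.max(np.abs(V - V.T), initial=0.0) > tol:
        raise ValueError("matrix is asymmetric beyond tolerance; cannot vectorize")
    iu = np.triu_indices(V.shape[0], k=1)
    return V[iu]


def unvectorize_edges(row: np.ndarray, N: int, diag: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_edges`; the diagonal is restored by
    convention."""
    W = np.zeros((N, N))
    iu = np.triu_indices(N, k=1)
    W[iu] = row
    W = W + W.T
    np.fill_diagonal(W, diag)
    return W


def clustering_coefficients(
    W: ConnectivityMatrix | np.ndarray, negative_weights: str = "abs"
) -> np.ndarray:
    """Weighted local clustering coefficient per node.

    On the weight matrix (|W| by default, or negatives zeroed with
    ``negative_weights="clip"``), zero diagonal, weights scaled by the
    maximum: ``c_u = (1/(k_u (k_u - 1))) * sum_{v,w} (what_uv what_uw
    what_vw)^(1/3)`` where ``k_u`` is the node degree (count of nonzero
    weights).  Nodes of degree < 2 get 0.
    """
    V = W.values if isinstance(W, ConnectivityMatrix) else np.asarray(W, float)
    A = np.abs(V.copy()) if negative_weights == "abs" else np.clip(V, 0.0, None)
    np.fill_diagonal(A, 0.0)
    mx = A.max()
    if mx == 0:
        return np.zeros(A.shape[0])
    A = A / mx
    k = (A > 0).sum(axis=1)
    cr = np.cbrt(A)
    tri = np.diag(cr @ cr @ cr)  # 2 * sum of triangle products per node
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c


def features_from_networks(
    networks: list[ConnectivityMatrix], feature_type: str
) -> FeatureMatrix:
    """Stack per-subject networks into an M x d feature matrix."""
    if feature_type == "edge_weights":
        rows = [vectorize_edges(W) for W in networks]
        N = networks[0].n_nodes
        index_map = [(i, j) for i in range(N) for j in range(i + 1, N)]
    elif feature_type == "clustering_coeff":
        rows = [clustering_coefficients(W) for W in networks]
        index_map = list(range(networks[0].n_nodes))
    else:
        raise ValueError(f"unknown feature_type {feature_type!r}")
    return FeatureMatrix(np.vstack(rows), index_map, feature_type)


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    """Outcome of a training-fold feature selection."""

    selected: np.ndarray  # original column indices, ascending
    p_values: np.ndarray | None = None
    lasso_lambda: float | None = None
    coefficients: np.ndarray | None = None  # lasso coefs over its input columns
    means: np.ndarray | None = None  # training-fold standardization (full d)
    stds: np.ndarray | None = None
    fallback: str | None = None  # set when an empty selection was rescued

    def transform(self, F: np.ndarray) -> np.ndarray:
        """Apply the stored standardization and column selection to new
        data (the test fold)."""
        Z = (F - self.means) / self.stds if self.means is not None else F
        return Z[:, self.selected]


def _standardization(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = F.mean(axis=0)
    sd = F.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def ttest_select(F: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> SelectionResult:
    """Two-sample pooled-variance t-test per feature; keep ``p < alpha``
    (uncorrected).  Features with zero pooled variance are excluded."""
    y = np.asarray(y)
    A, Bm = F[y == 1], F[y == -1]
    if len(A) == 0 or len(Bm) == 0:
        raise ValueError("both classes required in the training fold")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(A, Bm, axis=0, equal_var=True)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) with zero pooled variance excluded",
            stacklevel=2,
        )
    keep = np.where(np.isfinite(p) & (p < alpha))[0]
    mu, sd = _standardization(F)
    return SelectionResult(selected=keep, p_values=p, means=mu, stds=sd)


def lasso_select(
    F: np.ndarray, y: np.ndarray, lam: float = 0.05, max_iter: int = 50_000
) -> SelectionResult:
    """l1-penalized least squares of the +-1 labels on standardized
    features, mean-squared-error convention:

        min_w 1/(2M) ||y - b - Z w||^2 + lam ||w||_1

    Selected features are those with nonzero coefficients."""
    mu, sd = _standardization(F)
    Z = (F - mu) / sd
    model = Lasso(alpha=lam, fit_intercept=True, max_iter=max_iter, tol=1e-8)
    model.fit(Z, np.asarray(y, dtype=float))
    coef = model.coef_
    keep = np.where(coef != 0)[0]
    if keep.size == 0:
        warnings.warn("LASSO selected no features", stacklevel=2)
    return SelectionResult(
        selected=keep, lasso_lambda=lam, coefficients=coef, means=mu, stds=sd
    )


def select_features(
    F: np.ndarray,
    y: np.ndarray,
    mode: str = "ttest",
    alpha: float = 0.05,
    lam: float = 0.05,
) -> SelectionResult:
    """Selection dispatcher with the documented fallback chain.

    ``ttest_then_lasso`` composes the two steps (t-test survivors feed
    the LASSO); returned indices always refer to the original feature
    columns.  An empty final selection falls back (with a warning) to
    the previous stage's survivors and, ultimately, to all features.
    """
    d = F.shape[1]
    mu, sd = _standardization(F)
    if mode == "none":
        return SelectionResult(selected=np.arange(d), means=mu, stds=sd)
    if mode == "ttest":
        res = ttest_select(F, y, alpha)
        if res.selected.size == 0:
            warnings.warn("t-test selected no features; falling back to all", stacklevel=2)
            res = SelectionResult(
                selected=np.arange(d), p_values=res.p_values, means=mu, stds=sd,
                fallback="all",
            )
        return res
    if mode == "lasso":
        res = lasso_select(F, y, lam)
        if res.selected.size == 0:
            warnings.warn("falling back to all features", stacklevel=2)
            res = SelectionResult(
                selected=np.arange(d), lasso_lambda=lam, means=mu, stds=sd,
                fallback="all",
            )
        return res
    if mode == "ttest_then_lasso":
        first = ttest_select(F, y, alpha)
        survivors = first.selected
        if survivors.size == 0:
            warnings.warn(
                "t-test selected no features; falling back to all for LASSO",
                stacklevel=2,
            )
            survivors = np.arange(d)
        second = lasso_select(F[:, survivors], y, lam)
        if second.selected.size > 0:
            keep = survivors[second.selected]
            fb = None
        else:
            warnings.warn(
                "LASSO emptied the t-test survivors; keeping t-test selection",
                stacklevel=2,
            )
            keep = survivors
            fb = "ttest_survivors"
        return SelectionResult(
            selected=keep,
            p_values=first.p_values,
            lasso_lambda=lam,
            means=mu,
            stds=sd,
            fallback=fb,
        )
    raise ValueError(f"unknown selection mode {mode!r}")
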