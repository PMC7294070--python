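"""Pairwise correlation-based network constructors.

Four estimators that operate on Pearson correlations at increasing
"order":

* **PC** — plain pairwise correlation of the raw signals (low-order FC).
* **tHOFC** — correlation between two ROIs' *topographical FC profiles*
  (their rows of the PC matrix, excluding the entries belonging to the
  pair itself), i.e. similarity of whole-brain connectivity patterns.
* **aHOFC** — correlation between the tHOFC profile of one ROI and the
  PC profile of the other (an inter-level association); asymmetric by
  definition, then symmetrized by ``(W + W') / 2``.
* **dHOFC** — correlations between sliding-window *dynamic* FC series
  of edges.  Because an entry relates two edges (four ROIs), the raw
  object lives on N(N-1)/2 edge nodes; k-means clustering of the edge
  series reduces it to a K x K network on "edge-cluster" nodes.

All constructors are invariant to adding constants to, or positively
rescaling, any ROI signal.  Constant signals (globally, or within one
window) yield correlation 0 with a warning rather than NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .data import ConnectivityMatrix, Dataset, SubjectTimeSeries, symmetrize

__all__ = [
    "pearson_network",
    "thofc_network",
    "ahofc_network",
    "sliding_window_fc",
    "cluster_edge_series",
    "dhofc_network",
    "dhofc_networks",
    "DynamicEdgeSeries",
    "EdgeClustering",
    "pair_index",
    "safe_corrcoef",
]


def pair_index(N: int) -> list[tuple[int, int]]:
    """Column order of edge (upper-triangle) vectorizations: (i, j), i < j,
    lexicographic."""
    return [(i, j) for i in range(N) for j in range(i + 1, N)]


def safe_corrcoef(X: np.ndarray, warn: bool = True) -> np.ndarray:
    """Column-wise Pearson correlation with constant columns mapped to 0.

    Diagonal is 1 (also for constant columns, by convention); values are
    clipped to [-1, 1] against rounding.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        if warn:
            warnings.warn(
                f"constant signal in column(s) {np.where(const)[0].tolist()}; "
                "correlations set to 0",
                stacklevel=2,
            )
        Xs = X.copy()
        Xs[:, const] = 0.0
        Z = Xs - Xs.mean(axis=0)
        denom = np.where(const, 1.0, sd * np.sqrt(X.shape[0]))
        Z = Z / denom
        C = Z.T @ Z
        C[const, :] = 0.0
        C[:, const] = 0.0
    else:
        C = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def pearson_network(X: SubjectTimeSeries | np.ndarray) -> ConnectivityMatrix:
    """Low-order FC: pairwise Pearson correlation of the raw signals."""
    data = X.data if isinstance(X, SubjectTimeSeries) else np.asarray(X, dtype=float)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 time points for correlation")
    return ConnectivityMatrix(safe_corrcoef(data), method="PC")


def _profile_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equal-length profiles; 0 if either is
    constant."""
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def thofc_network(W_pc: ConnectivityMatrix | np.ndarray) -> ConnectivityMatrix:
    """Topographical-profile-similarity HOFC.

    Entry (i, j) is the correlation of the profiles ``{w_ik}`` and
    ``{w_jk}`` over ``k != i, j`` (both indices excluded, so profiles
    have length N - 2).
    """
    W = W_pc.values if isinstance(W_pc, ConnectivityMatrix) else np.asarray(W_pc, float)
    N = W.shape[0]
    if N < 4:
        raise ValueError("tHOFC requires at least 4 ROIs (profiles too short)")
    H = np.eye(N)
    for i in range(N):
        for j in range(i + 1, N):
            mask = np.ones(N, dtype=bool)
            mask[[i, j]] = False
            H[i, j] = H[j, i] = _profile_corr(W[i, mask], W[j, mask])
    return ConnectivityMatrix(H, method="tHOFC")


def ahofc_network(
    W_thofc: ConnectivityMatrix | np.ndarray,
    W_pc: ConnectivityMatrix | np.ndarray,
) -> ConnectivityMatrix:
    """Associated HOFC: correlation between the tHOFC profile of ROI i and
    the PC profile of ROI j over ``k != i, j``, then symmetrized by
    ``(W + W')/2``.  The diagonal is overwritten to 1 so all pairwise
    networks share the same convention (diagonals are never features).
    """
    H = W_thofc.values if isinstance(W_thofc, ConnectivityMatrix) else np.asarray(W_thofc, float)
    W = W_pc.values if isinstance(W_pc, ConnectivityMatrix) else np.asarray(W_pc, float)
    if H.shape != W.shape:
        raise ValueError("tHOFC and PC networks must have matching size")
    N = W.shape[0]
    if N < 4:
        raise ValueError("aHOFC requires at least 4 ROIs")
    A = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            mask = np.ones(N, dtype=bool)
            mask[[i, j]] = False
            A[i, j] = _profile_corr(H[i, mask], W[j, mask])
    A = symmetrize(A)
    np.fill_diagonal(A, 1.0)
    return ConnectivityMatrix(A, method="aHOFC")


# ---------------------------------------------------------------------------
# dHOFC: sliding windows -> edge series -> clustering -> K x K network
# ---------------------------------------------------------------------------


@dataclass
class DynamicEdgeSeries:
    """Windowed correlations of one subject: Theta rows x P = N(N-1)/2
    edge columns, with ``Theta = floor((T - L)/s) + 1``."""

    values: np.ndarray
    window_length: int
    step: int
    pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return self.values.shape[1]


def n_windows(T: int, L: int, s: int) -> int:
    """Theta = floor((T - L)/s) + 1."""
    if not 1 <= L <= T:
        raise ValueError(f"window length L={L} must satisfy 1 <= L <= T={T}")
    if s < 1:
        raise ValueError("step must be >= 1")
    return (T - L) // s + 1


def sliding_window_fc(
    X: SubjectTimeSeries | np.ndarray, L: int, s: int = 1
) -> DynamicEdgeSeries:
    """Dynamic FC: Pearson correlations within rectangular sliding windows.

    Window theta (0-based) covers rows ``[theta*s, theta*s + L)``; the
    last window ends at or before T.  A window containing a constant
    signal contributes 0 correlations for that signal (warning).
    """
    data = X.data if isinstance(X, SubjectTimeSeries) else np.asarray(X, dtype=float)
    T, N = data.shape
    if L < 3:
        raise ValueError("window length must be >= 3 for correlation")
    theta = n_windows(T, L, s)
    pairs = pair_index(N)
    iu = np.triu_indices(N, k=1)
    out = np.empty((theta, len(pairs)))
    warned = False
    for t in range(theta):
        seg = data[t * s : t * s + L]
        C = safe_corrcoef(seg, warn=not warned)
        if not warned and (seg.std(axis=0) == 0).any():
            warned = True
        out[t] = C[iu]
    return DynamicEdgeSeries(out, window_length=L, step=s, pairs=pairs)


@dataclass
class EdgeClustering:
    """Shared k-means assignment of edges to K clusters (the "high-order
    nodes" of dHOFC)."""

    K: int
    assignment: np.ndarray  # length P, values in 0..K-1
    pairs: list[tuple[int, int]]
    inertia: float = float("nan")

    def members(self, k: int) -> np.ndarray:
        return np.where(self.assignment == k)[0]


def cluster_edge_series(
    series: list[DynamicEdgeSeries],
    K: int,
    seed: int,
    n_init: int = 10,
) -> EdgeClustering:
    """k-means over edges, each represented by its z-scored dynamic FC
    series concatenated across subjects.

    The assignment is shared by all subjects.  With ``K == P`` every edge
    becomes its own cluster (identity assignment in edge order).
    """
    thetas = {d.n_windows for d in series}
    if len(thetas) > 1:
        raise ValueError("all subjects must share the same number of windows")
    P = series[0].n_edges
    if K > P:
        raise ValueError(f"K={K} exceeds the number of edges P={P}")
    feats = []
    for d in series:
        V = d.values.T  # P x Theta
        mu = V.mean(axis=1, keepdims=True)
        sd = V.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        feats.append((V - mu) / sd)
    F = np.hstack(feats)  # P x (Theta * M)
    if K == P:
        return EdgeClustering(K=K, assignment=np.arange(P), pairs=series[0].pairs, inertia=0.0)
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed % (2**31)).fit(F)
    assignment = km.labels_.astype(int)
    # guard against an empty cluster (sklearn relocates, but be explicit)
    for offset in range(1, 20):
        if len(np.unique(assignment)) == K:
            break
        km = KMeans(n_clusters=K, n_init=n_init, random_state=(seed + offset) % (2**31)).fit(F)
        assignment = km.labels_.astype(int)
    return EdgeClustering(K=K, assignment=assignment, pairs=series[0].pairs, inertia=float(km.inertia_) if K < P else 0.0)


def cluster_mean_series(d: DynamicEdgeSeries, clustering: EdgeClustering) -> np.ndarray:
    """Per-subject Theta x K matrix of cluster-averaged dynamic FC series."""
    out = np.empty((d.n_windows, clustering.K))
    for k in range(clustering.K):
        idx = clustering.members(k)
        out[:, k] = d.values[:, idx].mean(axis=1)
    return out


def dhofc_network(cluster_means: np.ndarray) -> ConnectivityMatrix:
    """K x K dHOFC network: correlations between cluster-mean dynamic FC
    series across windows."""
    cluster_means = np.asarray(cluster_means, dtype=float)
    if cluster_means.shape[0] < 3:
        raise ValueError("need at least 3 windows for dHOFC correlation")
    C = safe_corrcoef(cluster_means)
    return ConnectivityMatrix(C, method="dHOFC", node_semantics="edge_cluster")


def dhofc_networks(
    dataset: Dataset,
    L: int,
    K: int,
    seed: int,
    s: int = 1,
    subset: list[int] | None = None,
    clustering: EdgeClustering | None = None,
) -> tuple[list[ConnectivityMatrix], EdgeClustering]:
    """Full dHOFC pipeline for a cohort.

    Windows each subject, clusters the pooled edge series (unless a
    precomputed ``clustering`` is supplied, e.g. one fit on training
    subjects only), and returns one K x K network per subject plus the
    shared edge clustering.  Labels are never consulted.
    """
    dataset.require_equal_length("dHOFC")
    idx = range(dataset.n_subjects) if subset is None else subset
    series = [sliding_window_fc(dataset.subjects[i], L=L, s=s) for i in idx]
    if clustering is None:
        clustering = cluster_edge_series(series, K=K, seed=seed)
    nets = []
    for d in series:
        W = dhofc_network(cluster_mean_series(d, clustering))
        W.params.update({"L": L, "s": s, "K": K})
        nets.append(W)
    return nets, clustering
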