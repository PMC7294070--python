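"""Seeded synthetic-cohort generators.

Three generators emulate the statistical structure the rest of the
package assumes of region-averaged rs-fMRI time series, so every
pipeline component can be exercised without any external data:

* :func:`make_static_dataset` — two groups of subjects drawn from
  zero-mean multivariate normals with block-structured covariance; the
  patient group's covariance differs by ``+delta_r`` on a set of planted
  effect edges (the classification signal).
* :func:`make_dynamic_dataset` — piecewise-stationary signals following
  a seeded Markov state path between connectivity states; edges whose
  correlation toggles together across states form planted edge clusters
  (the structure dHOFC is designed to detect).
* :func:`make_sparse_representation_dataset` — signals built so each
  ROI is an exact sparse combination of other ROIs plus independent
  noise (proportional ROI pairs), providing a known support for the
  sparse-regression estimators.

All generators are pure functions of their spec and seed.  Covariances
are repaired to the nearest positive-definite matrix by eigenvalue
clipping at 1e-8 when a planted effect pushes them outside the cone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import Dataset, SubjectTimeSeries, write_time_series

__all__ = [
    "FixtureSpec",
    "make_static_dataset",
    "make_dynamic_dataset",
    "make_sparse_representation_dataset",
    "block_covariance",
    "nearest_pd",
    "write_dataset",
]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic cohort.

    ``m_per_group`` subjects per diagnostic group (labels +1 then -1),
    ``n_rois`` regions, ``t_points`` time points.  ``blocks`` maps each
    ROI to a module; within-module correlation ``r_within``, between
    ``r_between``.  ``effect_edges`` receive ``delta_r`` extra
    correlation in the +1 group.  Dynamic fixtures add ``n_states`` and
    ``dwell_mean`` (expected state dwell time, in time points); sparse
    fixtures use ``noise_sd`` and ``coef_range``.
    """

    m_per_group: int = 30
    n_rois: int = 20
    t_points: int = 150
    blocks: np.ndarray | None = None
    r_within: float = 0.4
    r_between: float = 0.05
    effect_edges: list = field(default_factory=list)
    delta_r: float = 0.6
    noise_sd: float = 0.05
    n_states: int = 2
    dwell_mean: int = 40
    coef_range: tuple = (0.8, 1.25)
    n_effect_pairs: int = 0
    coef_shift: float = 0.0
    seed: int = 0


def default_blocks(N: int, n_blocks: int = 4) -> np.ndarray:
    return np.arange(N) % n_blocks


def nearest_pd(S: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Nearest positive-definite repair by eigenvalue clipping at ``eps``
    (logged via a warning when a repair actually occurs)."""
    S = (S + S.T) / 2.0
    evals, evecs = np.linalg.eigh(S)
    if evals.min() >= eps:
        return S
    if evals.min() < -100 * eps:  # a real repair, not numerical dust
        warnings.warn(
            f"covariance repaired: minimum eigenvalue {evals.min():.3g} clipped to {eps}",
            stacklevel=2,
        )
    return (evecs * np.maximum(evals, eps)) @ evecs.T


def block_covariance(
    N: int,
    blocks: np.ndarray,
    r_within: float,
    r_between: float,
    effect_edges: list | None = None,
    delta_r: float = 0.0,
) -> np.ndarray:
    """Unit-diagonal block covariance, optionally with ``delta_r`` added
    on the given edges (clipped to keep entries inside (-1, 1))."""
    blocks = np.asarray(blocks)
    same = blocks[:, None] == blocks[None, :]
    S = np.where(same, r_within, r_between).astype(float)
    np.fill_diagonal(S, 1.0)
    if effect_edges and delta_r:
        for i, j in effect_edges:
            v = np.clip(S[i, j] + delta_r, -0.99, 0.99)
            S[i, j] = S[j, i] = v
    return nearest_pd(S)


def _draw_subjects(rng, cov, m, T, group_tag, start):
    # zero-padded global index first: lexicographic file order preserves
    # cohort order (the label file follows the same order)
    L = np.linalg.cholesky(cov)
    subs = []
    for k in range(m):
        Z = rng.standard_normal((T, cov.shape[0]))
        subs.append(
            SubjectTimeSeries(subject_id=f"sub{start + k:03d}{group_tag}", data=Z @ L.T)
        )
    return subs


def make_static_dataset(spec: FixtureSpec) -> tuple[Dataset, dict]:
    """Two-group stationary cohort with planted effect edges.

    Returns the dataset (labels +1 for the m_per_group patients, -1 for
    controls) and the ground truth (both covariances, effect edges).
    """
    rng = np.random.default_rng(spec.seed)
    N = spec.n_rois
    blocks = spec.blocks if spec.blocks is not None else default_blocks(N)
    cov_control = block_covariance(N, blocks, spec.r_within, spec.r_between)
    cov_patient = block_covariance(
        N, blocks, spec.r_within, spec.r_between, spec.effect_edges, spec.delta_r
    )
    patients = _draw_subjects(rng, cov_patient, spec.m_per_group, spec.t_points, "p", 0)
    controls = _draw_subjects(
        rng, cov_control, spec.m_per_group, spec.t_points, "c", spec.m_per_group
    )
    labels = np.concatenate(
        [np.ones(spec.m_per_group, dtype=int), -np.ones(spec.m_per_group, dtype=int)]
    )
    truth = {
        "cov_patient": cov_patient,
        "cov_control": cov_control,
        "effect_edges": list(spec.effect_edges),
        "blocks": blocks,
    }
    return Dataset(patients + controls, labels), truth


def _state_covariances(spec: FixtureSpec) -> list[np.ndarray]:
    """Per-state covariances: in state s, module ``s`` is strongly
    coherent while the other switching modules are incoherent; the last
    module keeps a constant moderate correlation in every state (its
    edges are the planted 'static' contrast)."""
    N = spec.n_rois
    blocks = spec.blocks if spec.blocks is not None else default_blocks(N, spec.n_states + 1)
    static_block = spec.n_states  # never switches
    covs = []
    for s in range(spec.n_states):
        S = np.full((N, N), spec.r_between)
        for b in range(spec.n_states + 1):
            sel = np.where(blocks == b)[0]
            if b == static_block:
                r = 0.5
            elif b == s:
                r = 0.9
            else:
                r = 0.0
            for i in sel:
                for j in sel:
                    if i != j:
                        S[i, j] = r
        np.fill_diagonal(S, 1.0)
        covs.append(nearest_pd(S))
    return covs


def make_dynamic_dataset(spec: FixtureSpec) -> tuple[Dataset, dict]:
    """Piecewise-stationary cohort following a seeded Markov state path.

    With a single state this reduces distributionally to a stationary
    draw.  Dwell times are geometric with mean ``dwell_mean``; all
    subjects share the state dynamics (independent paths).  The truth
    records each subject's state path and the block structure whose
    within-block edges co-switch.
    """
    if spec.n_states < 1:
        raise ValueError("need at least one state")
    rng = np.random.default_rng(spec.seed)
    N, T = spec.n_rois, spec.t_points
    blocks = spec.blocks if spec.blocks is not None else default_blocks(N, spec.n_states + 1)
    spec2 = FixtureSpec(**{**spec.__dict__, "blocks": blocks})
    covs = _state_covariances(spec2) if spec.n_states > 1 else [
        block_covariance(N, blocks, spec.r_within, spec.r_between)
    ]
    chols = [np.linalg.cholesky(c) for c in covs]
    p_stay = 1.0 - 1.0 / max(spec.dwell_mean, 2)
    subjects = []
    paths = []
    M = 2 * spec.m_per_group
    for m in range(M):
        state = int(rng.integers(len(covs)))
        path = np.empty(T, dtype=int)
        X = np.empty((T, N))
        for t in range(T):
            if t > 0 and rng.random() > p_stay:
                state = int(rng.integers(len(covs)))
            path[t] = state
            X[t] = chols[state] @ rng.standard_normal(N)
        subjects.append(SubjectTimeSeries(subject_id=f"dyn{m:03d}", data=X))
        paths.append(path)
    labels = np.concatenate(
        [np.ones(spec.m_per_group, dtype=int), -np.ones(spec.m_per_group, dtype=int)]
    )
    truth = {"state_paths": paths, "blocks": blocks, "covs": covs}
    return Dataset(subjects, labels), truth


def make_sparse_representation_dataset(
    spec: FixtureSpec,
) -> tuple[Dataset, dict]:
    """Cohort in which each ROI is an exact sparse combination of the
    others plus noise.

    ROIs are paired: ``x_{2k+1} = c_k x_{2k} + noise_sd * eps`` with
    ``c_k`` drawn from ``coef_range``.  The ground-truth representation
    matrix has ``w[2k, 2k+1] = c_k`` and ``w[2k+1, 2k] = 1/c_k`` (each
    member of a pair represents the other), so at ``noise_sd = 0`` the
    representation residual ``||X - XW||`` is exactly zero.  The true
    support is the set of pair edges.

    When ``n_effect_pairs > 0``, the first ``n_effect_pairs`` pair
    coefficients are shifted by ``+coef_shift`` for the +1 group and
    ``-coef_shift`` for the -1 group: a group difference carried by the
    sparse representation itself.
    """
    if spec.n_rois % 2:
        raise ValueError("sparse fixture needs an even number of ROIs")
    rng = np.random.default_rng(spec.seed)
    N, T, M = spec.n_rois, spec.t_points, 2 * spec.m_per_group
    subjects = []
    Ws = []
    for m in range(M):
        label = 1 if m < spec.m_per_group else -1
        X = np.empty((T, N))
        W = np.zeros((N, N))
        for k in range(N // 2):
            i, j = 2 * k, 2 * k + 1
            base = rng.standard_normal(T)
            c = rng.uniform(*spec.coef_range)
            if k < spec.n_effect_pairs:
                c = max(c + label * spec.coef_shift, 0.1)
            X[:, i] = base
            X[:, j] = c * base + spec.noise_sd * rng.standard_normal(T)
            W[i, j] = c
            W[j, i] = 1.0 / c
        rho = np.max(np.abs(np.linalg.eigvals(W)))
        if rho > 1.0 + 1e-9:
            raise ValueError(f"unstable ground-truth representation (spectral radius {rho:.3f})")
        subjects.append(SubjectTimeSeries(subject_id=f"spr{m:03d}", data=X))
        Ws.append(W)
    labels = np.concatenate(
        [np.ones(spec.m_per_group, dtype=int), -np.ones(spec.m_per_group, dtype=int)]
    )
    support = np.zeros((N, N), dtype=bool)
    for k in range(N // 2):
        support[2 * k, 2 * k + 1] = support[2 * k + 1, 2 * k] = True
    truth = {"true_W": Ws, "support": support}
    return Dataset(subjects, labels), truth


def write_dataset(dataset: Dataset, out_dir: str | Path, truth: dict | None = None) -> None:
    """Write per-subject CSV time series plus a label file (and the
    planted support, when present) — directly consumable by the CLI."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in dataset.subjects:
        write_time_series(s.data, out / f"{s.subject_id}.csv")
    if dataset.labels is not None:
        (out / "labels.txt").write_text("\n".join(str(v) for v in dataset.labels) + "\n")
    if truth and "support" in truth:
        np.savetxt(out / "true_support.txt", truth["support"].astype(int), fmt="%d")
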