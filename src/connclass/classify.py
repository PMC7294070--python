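"""Linear-SVM classification, cross-validation schemes, nested CV with
parameter-grid optimization, the metric battery and run reporting.

The pipeline per cross-validation fold is always: slice the per-subject
networks -> extract features -> fit selection on the training fold only
-> standardize with training statistics -> train a linear soft-margin
SVM (C = 1 by default) -> score the held-out subjects.  Network
construction itself never sees labels, so per-parameter networks are
built once and reused across folds (a strict mode instead rebuilds the
group-level constructions from training subjects only).

Three CV schemes: leave-one-out (pooled held-out scores give a single
report), repeated stratified 10-fold (metrics averaged over folds and
repetitions; AUC pooled within a repetition, averaged across them), and
leave-group-out (e.g. leave-center-out; pooled like LOOCV).

For methods with free parameters, nested CV evaluates every grid
combination end-to-end inside each outer training set; the inner winner
(ties broken by grid order) trains the outer model.  How often each
combination wins is reported as the *parameter selection occurrence*
(robustness); a separate LOOCV sweep per combination yields the
sensitivity bars and the *suggested parameters* (peak bar).
"""

from __future__ import annotations

import datetime
import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import (
    ConnectivityMatrix,
    Dataset,
    LogRecord,
    RunConfig,
    TYPE_II_METHODS,
    symmetrize,
)
from .features import FeatureMatrix, SelectionResult, features_from_networks, select_features
from .pairwise import (
    ahofc_network,
    cluster_edge_series,
    dhofc_networks,
    pearson_network,
    sliding_window_fc,
    thofc_network,
)
from .sparse import SolverConfig, construct_sparse_networks

__all__ = [
    "LinearClassifier",
    "EvaluationReport",
    "ParameterReport",
    "FeatureImportance",
    "CVResult",
    "train_svm",
    "evaluate",
    "construct_networks",
    "run_cv",
    "run_nested_cv",
    "parameter_sensitivity",
    "compute_feature_importance",
    "group_mean_networks",
    "grid_combinations",
    "write_log",
]

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------


@dataclass
class LinearClassifier:
    """Linear soft-margin SVM decision rule ``score = w . f + b``;
    positive score predicts class +1 (patient)."""

    w: np.ndarray
    b: float
    C: float = 1.0

    def decision(self, F: np.ndarray) -> np.ndarray:
        return np.asarray(F, dtype=float) @ self.w + self.b


def train_svm(F: np.ndarray, y: np.ndarray, C: float = 1.0) -> LinearClassifier:
    """Fit a linear soft-margin SVM (hinge loss, penalty C)."""
    F = np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=int)
    if C <= 0:
        raise ValueError("C must be positive")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to train the SVM")
    if F.ndim != 2 or F.shape[1] == 0:
        raise ValueError("empty feature matrix")
    if np.all(F.std(axis=0) == 0):
        raise ValueError("all features constant across training subjects")
    model = SVC(kernel="linear", C=C, tol=1e-8)
    model.fit(F, y)
    return LinearClassifier(w=model.coef_.ravel().copy(), b=float(model.intercept_[0]), C=C)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Confusion counts at the fixed threshold plus the metric battery.

    The identities ``BAC = (SEN + SPE)/2``, ``Youden = SEN + SPE - 1``,
    ``F = 2 * precision * SEN / (precision + SEN)`` and
    ``ACC = (TP + TN)/M`` hold exactly; AUC is the rank (Mann-Whitney)
    statistic with ties counted 1/2.
    """

    TP: int
    TN: int
    FP: int
    FN: int
    ACC: float
    AUC: float
    SEN: float
    SPE: float
    precision: float
    BAC: float
    youden: float
    f_score: float
    scores: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    y_true: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    roc_fpr: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    roc_tpr: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def metrics_dict(self) -> dict:
        return {
            "ACC": self.ACC,
            "AUC": self.AUC,
            "SEN": self.SEN,
            "SPE": self.SPE,
            "precision": self.precision,
            "BAC": self.BAC,
            "youden": self.youden,
            "f_score": self.f_score,
        }


def evaluate(y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.0) -> EvaluationReport:
    """Score a set of held-out predictions.

    Class +1 is predicted where ``score >= threshold`` (threshold fixed
    at 0 for the confusion matrix); AUC uses the raw scores.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(y_true)
    if len(classes) < 2:
        raise ValueError("AUC undefined: need both classes among the evaluated subjects")
    pred = np.where(scores >= threshold, 1, -1)
    TP = int(np.sum((pred == 1) & (y_true == 1)))
    TN = int(np.sum((pred == -1) & (y_true == -1)))
    FP = int(np.sum((pred == 1) & (y_true == -1)))
    FN = int(np.sum((pred == -1) & (y_true == 1)))
    M = TP + TN + FP + FN
    SEN = TP / (TP + FN) if TP + FN else 0.0
    SPE = TN / (TN + FP) if TN + FP else 0.0
    prec = TP / (TP + FP) if TP + FP else 0.0
    ACC = (TP + TN) / M
    BAC = (SEN + SPE) / 2.0
    youden = SEN + SPE - 1.0
    f_score = 2.0 * prec * SEN / (prec + SEN) if prec + SEN else 0.0
    AUC = float(roc_auc_score(y_true, scores))
    fpr, tpr, _ = roc_curve(y_true, scores)
    return EvaluationReport(
        TP=TP, TN=TN, FP=FP, FN=FN, ACC=ACC, AUC=AUC, SEN=SEN, SPE=SPE,
        precision=prec, BAC=BAC, youden=youden, f_score=f_score,
        scores=scores, y_true=y_true, roc_fpr=fpr, roc_tpr=tpr,
    )


# ---------------------------------------------------------------------------
# Network construction dispatcher
# ---------------------------------------------------------------------------


def construct_networks(
    dataset: Dataset,
    method: str,
    params: dict | None = None,
    seed: int = 0,
    window_step: int = 1,
    solver_cfg: SolverConfig | None = None,
    subset: list[int] | None = None,
):
    """Construct one network per subject with the given method/parameters.

    Labels are never consulted.  Returns ``(networks, aux)`` where
    ``aux`` is the shared edge clustering for dHOFC and None otherwise.
    """
    params = dict(params or {})
    if method == "PC":
        return [pearson_network(s) for s in _subjects(dataset, subset)], None
    if method == "tHOFC":
        return [thofc_network(pearson_network(s)) for s in _subjects(dataset, subset)], None
    if method == "aHOFC":
        out = []
        for s in _subjects(dataset, subset):
            pc = pearson_network(s)
            out.append(ahofc_network(thofc_network(pc), pc))
        return out, None
    if method == "dHOFC":
        nets, clustering = dhofc_networks(
            dataset,
            L=int(params["L"]),
            K=int(params["K"]),
            seed=seed,
            s=int(params.get("s", window_step)),
            subset=subset,
            clustering=params.get("_clustering"),
        )
        return nets, clustering
    nets = construct_sparse_networks(dataset, method, params, cfg=solver_cfg, subset=subset)
    return nets, None


def _subjects(dataset: Dataset, subset):
    if subset is None:
        return dataset.subjects
    return [dataset.subjects[i] for i in subset]


def grid_combinations(parameter_grid: dict) -> list[dict]:
    """Enumerate grid combinations in the user-given key and value order
    (lexicographic over the grid as entered — the tie-break order)."""
    if not parameter_grid:
        return [{}]
    keys = list(parameter_grid.keys())
    return [dict(zip(keys, combo)) for combo in itertools.product(*parameter_grid.values())]


# ---------------------------------------------------------------------------
# Feature importance
# ---------------------------------------------------------------------------


@dataclass
class FeatureImportance:
    """Mean signed SVM weight per original feature (over the CV runs in
    which it was selected) and its selection occurrence count."""

    mean_weight: np.ndarray
    occurrence: np.ndarray
    n_runs: int
    index_map: list
    feature_type: str

    def selected_mask(self) -> np.ndarray:
        return self.occurrence > 0

    def to_matrix(self, N: int) -> np.ndarray:
        """Edge-feature importance reshaped to a symmetric N x N matrix
        (never-selected features are 0)."""
        if self.feature_type != "edge_weights":
            raise ValueError("matrix form only applies to edge features")
        W = np.zeros((N, N))
        for col, (i, j) in enumerate(self.index_map):
            W[i, j] = W[j, i] = self.mean_weight[col]
        return W

    def occurrence_matrix(self, N: int) -> np.ndarray:
        if self.feature_type != "edge_weights":
            raise ValueError("matrix form only applies to edge features")
        W = np.zeros((N, N))
        for col, (i, j) in enumerate(self.index_map):
            W[i, j] = W[j, i] = self.occurrence[col]
        return W


def compute_feature_importance(
    fold_records: list[tuple[SelectionResult, LinearClassifier]],
    n_features: int,
    index_map: list,
    feature_type: str,
) -> FeatureImportance:
    """Aggregate per-fold SVM weights and selections over original
    feature columns.  Never-selected features report weight 0 (masked by
    occurrence 0)."""
    wsum = np.zeros(n_features)
    occ = np.zeros(n_features, dtype=int)
    for sel, clf in fold_records:
        wsum[sel.selected] += clf.w
        occ[sel.selected] += 1
    mean_w = np.divide(wsum, occ, out=np.zeros(n_features), where=occ > 0)
    return FeatureImportance(
        mean_weight=mean_w,
        occurrence=occ,
        n_runs=len(fold_records),
        index_map=index_map,
        feature_type=feature_type,
    )


def dhofc_importance_matrices(
    importance: FeatureImportance, clustering, N: int
) -> list[np.ndarray]:
    """For dHOFC (features = cluster nodes): one N x N matrix per cluster
    marking its member edges with the cluster's importance weight."""
    mats = []
    for k in range(clustering.K):
        W = np.zeros((N, N))
        val = importance.mean_weight[k]
        for e in clustering.members(k):
            i, j = clustering.pairs[e]
            W[i, j] = W[j, i] = val
        mats.append(W)
    return mats


# ---------------------------------------------------------------------------
# Fold machinery
# ---------------------------------------------------------------------------


def _loocv_folds(M: int) -> list[tuple[np.ndarray, np.ndarray]]:
    idx = np.arange(M)
    return [(np.delete(idx, i), np.array([i])) for i in range(M)]


def _kfold_folds(y: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold; re-drawn (new seed offset) if a training fold
    ends up single-class."""
    for attempt in range(100):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=(seed + 7919 * attempt) % (2**31))
        folds = list(skf.split(np.zeros_like(y), y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            return [(np.asarray(tr), np.asarray(te)) for tr, te in folds]
    raise RuntimeError("could not draw a partition with both classes in every training fold")


def _group_folds(groups: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    groups = np.asarray(groups)
    idx = np.arange(groups.size)
    out = []
    for g in np.unique(groups):
        te = idx[groups == g]
        out.append((idx[groups != g], te))
    return out


def _fit_score_fold(
    F: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    config: RunConfig,
) -> tuple[SelectionResult, LinearClassifier, np.ndarray]:
    sel = select_features(
        F[train], y[train], mode=config.selection,
        alpha=config.alpha_ttest, lam=config.lambda_lasso,
    )
    Ztr = sel.transform(F[train])
    if np.all(Ztr.std(axis=0) == 0):
        # degenerate fold (e.g. an over-penalized grid value zeroed every
        # network): fall back to the majority-class rule so the grid value
        # scores at chance instead of aborting the run
        warnings.warn("constant training features; using majority-class rule", stacklevel=2)
        maj = 1 if np.sum(y[train] == 1) >= np.sum(y[train] == -1) else -1
        clf = LinearClassifier(w=np.zeros(Ztr.shape[1]), b=float(maj) * 1e-6, C=config.svm_C)
    else:
        clf = train_svm(Ztr, y[train], C=config.svm_C)
    scores = clf.decision(sel.transform(F[test]))
    return sel, clf, scores


@dataclass
class CVResult:
    """Outcome of one cross-validated evaluation."""

    metrics: dict
    report: EvaluationReport | None
    fold_reports: list
    importance: FeatureImportance
    scores: np.ndarray | None = None  # pooled held-out scores (loocv / lgo)


def _pooled_cv(F, y, folds, config) -> CVResult:
    M = len(y)
    scores = np.empty(M)
    records = []
    for train, test in folds:
        sel, clf, sc = _fit_score_fold(F.values, y, train, test, config)
        scores[test] = sc
        records.append((sel, clf))
    report = evaluate(y, scores)
    imp = compute_feature_importance(records, F.n_features, F.index_map, F.feature_type)
    return CVResult(
        metrics=report.metrics_dict(), report=report,
        fold_reports=[report], importance=imp, scores=scores,
    )


def _repeated_kfold_cv(F, y, config) -> CVResult:
    records = []
    fold_reports = []
    per_rep_metrics = []
    for r in range(config.repeats):
        folds = _kfold_folds(y, config.k_folds, config.seed + r)
        rep_scores = np.empty(len(y))
        rep_fold_metrics = []
        for train, test in folds:
            sel, clf, sc = _fit_score_fold(F.values, y, train, test, config)
            rep_scores[test] = sc
            records.append((sel, clf))
            if len(np.unique(y[test])) == 2:
                rep_fold_metrics.append(evaluate(y[test], sc).metrics_dict())
                fold_reports.append(evaluate(y[test], sc))
        rep_report = evaluate(y, rep_scores)  # pooled within the repetition
        m = {
            k: float(np.mean([fm[k] for fm in rep_fold_metrics]))
            for k in rep_fold_metrics[0]
        } if rep_fold_metrics else rep_report.metrics_dict()
        m["AUC"] = rep_report.AUC  # AUC pooled within a repetition
        per_rep_metrics.append(m)
    metrics = {k: float(np.mean([m[k] for m in per_rep_metrics])) for k in per_rep_metrics[0]}
    imp = compute_feature_importance(records, F.n_features, F.index_map, F.feature_type)
    return CVResult(metrics=metrics, report=None, fold_reports=fold_reports, importance=imp)


def run_cv(
    dataset: Dataset,
    config: RunConfig,
    params: dict | None = None,
    networks: list[ConnectivityMatrix] | None = None,
    groups: np.ndarray | None = None,
) -> CVResult:
    """Cross-validated classification at fixed construction parameters.

    ``networks`` may be supplied directly (e.g. externally constructed);
    otherwise they are built from the dataset (label-free, so built once
    and sliced per fold).
    """
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    y = dataset.labels
    if networks is None:
        networks, _ = construct_networks(
            dataset, config.method, params, seed=config.seed,
            window_step=config.window_step,
        )
    F = features_from_networks(networks, config.feature_type)
    return _dispatch_cv(F, y, config, groups)


def _dispatch_cv(F: FeatureMatrix, y: np.ndarray, config: RunConfig, groups=None) -> CVResult:
    if config.cv_scheme == "loocv":
        return _pooled_cv(F, y, _loocv_folds(len(y)), config)
    if config.cv_scheme == "kfold":
        return _repeated_kfold_cv(F, y, config)
    if config.cv_scheme == "leave_group_out":
        if groups is None:
            raise ValueError("leave_group_out requires a group assignment")
        return _pooled_cv(F, y, _group_folds(groups), config)
    raise ValueError(f"unknown cv_scheme {config.cv_scheme!r}")


def run_cv_networks(
    networks: list[ConnectivityMatrix],
    labels: np.ndarray,
    config: RunConfig,
    groups: np.ndarray | None = None,
) -> CVResult:
    """Cross-validated classification straight from precomputed networks
    (e.g. constructed by another tool); no time series required."""
    y = np.asarray(labels, dtype=int)
    if len(networks) != y.size:
        raise ValueError("one network per subject required")
    F = features_from_networks(networks, config.feature_type)
    return _dispatch_cv(F, y, config, groups)


# ---------------------------------------------------------------------------
# Nested CV
# ---------------------------------------------------------------------------


@dataclass
class ParameterReport:
    """Grid-level reporting: sensitivity bars, selection occurrences and
    the suggested parameters."""

    combos: list
    sensitivity_accuracy: list | None = None
    selection_occurrence: np.ndarray | None = None
    suggested: dict | None = None

    def occurrence_table(self) -> list[tuple[dict, int]]:
        if self.selection_occurrence is None:
            return []
        return [(c, int(n)) for c, n in zip(self.combos, self.selection_occurrence)]


@dataclass
class NestedCVResult:
    metrics: dict
    report: EvaluationReport | None
    parameter_report: ParameterReport
    importance: FeatureImportance
    best_combo: dict
    group_means: tuple[ConnectivityMatrix, ConnectivityMatrix] | None = None


def _features_for_combos(dataset, config, combos):
    """Build (and cache) per-combination networks and features from the
    whole cohort — valid because construction never touches labels."""
    nets = {}
    feats = {}
    for c, combo in enumerate(combos):
        networks, _ = construct_networks(
            dataset, config.method, combo, seed=config.seed,
            window_step=config.window_step,
        )
        nets[c] = networks
        feats[c] = features_from_networks(networks, config.feature_type)
    return nets, feats


def _strict_features_for_fold(dataset, config, combos, train, test):
    """Strict mode: group-level constructions (GSR/SSGSR joint solve,
    dHOFC edge clustering) are re-fit on training subjects only; test
    subjects are then mapped without influencing the fit.

    For per-subject methods this coincides with the default mode.
    """
    M = dataset.n_subjects
    feats = {}
    for c, combo in enumerate(combos):
        if config.method == "dHOFC":
            train_series = [
                sliding_window_fc(dataset.subjects[i], L=int(combo["L"]), s=config.window_step)
                for i in train
            ]
            clustering = cluster_edge_series(train_series, K=int(combo["K"]), seed=config.seed)
            nets, _ = dhofc_networks(
                dataset, L=int(combo["L"]), K=int(combo["K"]), seed=config.seed,
                s=config.window_step, clustering=clustering,
            )
        elif config.method in ("GSR", "SSGSR"):
            train_nets = construct_sparse_networks(
                dataset, config.method, combo, subset=list(train)
            )
            # test subjects: least-squares refit restricted to the joint
            # support learned on the training cohort
            support = np.abs(train_nets[0].extras["pre_symmetrization"]) > 1e-10
            nets_all: list = [None] * M
            for k, i in enumerate(train):
                nets_all[i] = train_nets[k]
            from .sparse import normalize_signals

            for i in test:
                X = normalize_signals(dataset.subjects[i].data)
                N = X.shape[1]
                W = np.zeros((N, N))
                for col in range(N):
                    keep = [j for j in range(N) if j != col]
                    rows = support[keep, col]
                    if rows.any():
                        D = X[:, keep][:, rows]
                        w, *_ = np.linalg.lstsq(D, X[:, col], rcond=None)
                        W[np.array(keep)[rows], col] = w
                nets_all[i] = ConnectivityMatrix(
                    symmetrize(W), method=config.method, params=dict(combo)
                )
            nets = nets_all
        else:
            nets, _ = construct_networks(
                dataset, config.method, combo, seed=config.seed,
                window_step=config.window_step,
            )
        feats[c] = features_from_networks(nets, config.feature_type)
    return feats


def _inner_accuracy(combo_feats, y, train, config) -> float:
    """Accuracy of one grid combination on the inner CV over ``train``."""
    y_tr = y[train]
    if config.inner_cv == "loocv":
        inner = _loocv_folds(len(train))
    else:
        inner = _kfold_folds(y_tr, min(config.inner_k_folds, len(train)), config.seed)
    correct = 0
    total = 0
    for itr, ite in inner:
        tr_idx = train[itr]
        te_idx = train[ite]
        if len(np.unique(y[tr_idx])) < 2:
            continue
        _, _, sc = _fit_score_fold(combo_feats.values, y, tr_idx, te_idx, config)
        pred = np.where(sc >= 0, 1, -1)
        correct += int(np.sum(pred == y[te_idx]))
        total += len(te_idx)
    return correct / total if total else 0.0


def run_nested_cv(
    dataset: Dataset,
    config: RunConfig,
    groups: np.ndarray | None = None,
) -> NestedCVResult:
    """Nested cross-validation for parameter-requiring methods.

    Every grid combination is evaluated end-to-end (construction ->
    features -> selection -> SVM) by an inner CV confined to each outer
    training set; outer test subjects never influence the inner choice.
    """
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    if config.method in TYPE_II_METHODS and not config.parameter_grid:
        raise ValueError(f"{config.method} requires a non-empty parameter grid")
    y = dataset.labels
    combos = grid_combinations(config.parameter_grid)
    if not config.strict_fold_networks:
        nets_by_combo, feats_by_combo = _features_for_combos(dataset, config, combos)
    else:
        nets_by_combo = None

    M = dataset.n_subjects
    if config.cv_scheme == "loocv":
        outer = _loocv_folds(M)
    elif config.cv_scheme == "kfold":
        outer = _kfold_folds(y, config.k_folds, config.seed)
    elif config.cv_scheme == "leave_group_out":
        if groups is None:
            raise ValueError("leave_group_out requires a group assignment")
        outer = _group_folds(groups)
    else:
        raise ValueError(f"unknown cv_scheme {config.cv_scheme!r}")

    occurrences = np.zeros(len(combos), dtype=int)
    scores = np.empty(M)
    records = []
    feature_shape = None
    for train, test in outer:
        if config.strict_fold_networks:
            feats_by_combo = _strict_features_for_fold(dataset, config, combos, train, test)
        best_c, best_acc = 0, -1.0
        for c in range(len(combos)):
            acc = _inner_accuracy(feats_by_combo[c], y, train, config)
            if acc > best_acc + 1e-12:
                best_c, best_acc = c, acc
        occurrences[best_c] += 1
        Fb = feats_by_combo[best_c]
        feature_shape = (Fb.n_features, Fb.index_map, Fb.feature_type)
        sel, clf, sc = _fit_score_fold(Fb.values, y, train, test, config)
        scores[test] = sc
        records.append((sel, clf))

    report = evaluate(y, scores)
    imp = compute_feature_importance(records, *feature_shape)
    param_report = ParameterReport(combos=combos, selection_occurrence=occurrences)

    best_combo = combos[int(np.argmax(occurrences))]  # ties -> grid order
    group_means = None
    if nets_by_combo is not None and dataset.labels is not None:
        best_idx = int(np.argmax(occurrences))
        group_means = group_mean_networks(nets_by_combo[best_idx], y)
    return NestedCVResult(
        metrics=report.metrics_dict(),
        report=report,
        parameter_report=param_report,
        importance=imp,
        best_combo=best_combo,
        group_means=group_means,
    )


def parameter_sensitivity(
    dataset: Dataset,
    config: RunConfig,
    grid: dict | None = None,
) -> ParameterReport:
    """Full-LOOCV accuracy for every grid combination (the sensitivity
    bar plot); the peak bar gives the *suggested parameters* (ties ->
    first combination in grid order)."""
    grid = grid if grid is not None else config.parameter_grid
    combos = grid_combinations(grid)
    accs = []
    loocv_config = RunConfig(**{**config.to_dict(), "cv_scheme": "loocv", "parameter_grid": {}})
    for combo in combos:
        res = run_cv(dataset, loocv_config, params=combo)
        accs.append(res.metrics["ACC"])
    best = int(np.argmax(accs))
    return ParameterReport(
        combos=combos,
        sensitivity_accuracy=[float(a) for a in accs],
        suggested=combos[best],
    )


# ---------------------------------------------------------------------------
# Group means and logging
# ---------------------------------------------------------------------------


def group_mean_networks(
    networks: list[ConnectivityMatrix], labels: np.ndarray
) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    """Elementwise mean network per label group (+1 first, then -1)."""
    labels = np.asarray(labels)
    out = []
    for lab in (1, -1):
        mats = [networks[i].values for i in np.where(labels == lab)[0]]
        mean = np.mean(mats, axis=0)
        out.append(
            ConnectivityMatrix(
                mean,
                method=networks[0].method,
                params=dict(networks[0].params),
                node_semantics=networks[0].node_semantics,
            )
        )
    return out[0], out[1]


def write_log(
    path: str | Path,
    config: RunConfig,
    metrics: dict,
    parameter_report: ParameterReport | None = None,
    outputs: dict | None = None,
    timestamp: bool = True,
) -> LogRecord:
    """Write the run log as text (``path``) and JSON (``path + .json``).

    The JSON document round-trips losslessly into :class:`LogRecord`;
    the timestamp is excluded from reproducibility comparisons.
    """
    path = Path(path)
    record = LogRecord(
        config=config.to_dict(),
        metrics={k: float(v) for k, v in metrics.items()},
        suggested_params=parameter_report.suggested if parameter_report else None,
        selection_occurrence=(
            [[c, int(n)] for c, n in parameter_report.occurrence_table()]
            if parameter_report and parameter_report.selection_occurrence is not None
            else None
        ),
        sensitivity=(
            [[c, float(a)] for c, a in zip(parameter_report.combos, parameter_report.sensitivity_accuracy)]
            if parameter_report and parameter_report.sensitivity_accuracy is not None
            else None
        ),
        outputs=dict(outputs or {}),
        software_version=__version__,
        timestamp=datetime.datetime.now().isoformat() if timestamp else "",
    )
    path.write_text(record.to_text())
    path.with_suffix(path.suffix + ".json").write_text(record.to_json())
    return record
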