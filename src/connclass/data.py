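"""Data model, file IO, configuration, logging and memory estimation.

The package operates on cohorts of region-averaged rs-fMRI time series:
one ``T x N`` matrix per subject (T time points, N regions of interest),
plus a vector of diagnostic labels coded ``+1`` (patient) / ``-1``
(control).  Everything downstream — network construction, feature
extraction, cross-validated classification — consumes the containers
defined here.

Text formats only: time series and networks are delimited numeric
tables (comma, tab or whitespace; optional single header row), labels
are one integer per line, and run logs are written both as a
human-readable text file and as a JSON document that round-trips
losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("connclass")

__all__ = [
    "SubjectTimeSeries",
    "Dataset",
    "ConnectivityMatrix",
    "RunConfig",
    "LogRecord",
    "PAIRWISE_METHODS",
    "SPARSE_METHODS",
    "TYPE_I_METHODS",
    "TYPE_II_METHODS",
    "METHODS",
    "read_time_series",
    "read_labels",
    "write_time_series",
    "write_network",
    "read_network",
    "estimate_memory",
    "symmetrize",
]

# ---------------------------------------------------------------------------
# Method registry
# ---------------------------------------------------------------------------

#: Pairwise correlation-based constructors (N x N, or K x K for dHOFC).
PAIRWISE_METHODS = ("PC", "tHOFC", "aHOFC", "dHOFC")

#: Sparse-representation (regression-based) constructors.  "SGR" is an
#: alias accepted for WSGR.
SPARSE_METHODS = ("SR", "WSR", "WSGR", "GSR", "SSGSR", "SLR")

#: Type I: no free parameter to optimize.  Type II: nested CV required.
TYPE_I_METHODS = ("PC", "tHOFC", "aHOFC")
TYPE_II_METHODS = ("dHOFC", "SR", "WSR", "WSGR", "GSR", "SSGSR", "SLR")

METHODS = PAIRWISE_METHODS + SPARSE_METHODS

_METHOD_ALIASES = {"SGR": "WSGR"}


def canonical_method(name: str) -> str:
    """Resolve a method name (case-insensitive, aliases allowed)."""
    for m in METHODS:
        if name.upper() == m.upper():
            return m
    if name.upper() in _METHOD_ALIASES:
        return _METHOD_ALIASES[name.upper()]
    raise ValueError(f"unknown network construction method: {name!r}")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class SubjectTimeSeries:
    """One subject's region-averaged signal matrix (T time points x N ROIs)."""

    subject_id: str
    data: np.ndarray
    constant_columns: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"{self.subject_id}: time series must be 2-D")
        T, N = self.data.shape
        if T < 5:
            raise ValueError(f"{self.subject_id}: need at least 5 time points, got {T}")
        if N < 3:
            raise ValueError(f"{self.subject_id}: need at least 3 ROIs, got {N}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"{self.subject_id}: non-finite values in time series")
        const = tuple(int(j) for j in np.where(self.data.std(axis=0) == 0)[0])
        if const:
            warnings.warn(
                f"{self.subject_id}: constant signal in ROI column(s) {const}; "
                "their correlations will be set to 0",
                stacklevel=2,
            )
        self.constant_columns = const

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class Dataset:
    """An ordered cohort of subjects with optional +1/-1 labels."""

    subjects: list[SubjectTimeSeries]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("empty dataset")
        ns = {s.n_rois for s in self.subjects}
        if len(ns) > 1:
            offenders = {s.subject_id: s.n_rois for s in self.subjects}
            raise ValueError(f"inconsistent ROI counts across subjects: {offenders}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.subjects),):
                raise ValueError(
                    f"label vector length {self.labels.size} != "
                    f"number of subjects {len(self.subjects)}"
                )
            bad = set(np.unique(self.labels)) - {1, -1}
            if bad:
                raise ValueError(f"labels must be +1/-1, found {sorted(bad)}")
            if len(np.unique(self.labels)) < 2:
                raise ValueError("both classes required (+1 and -1)")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_rois(self) -> int:
        return self.subjects[0].n_rois

    def equal_length(self) -> bool:
        return len({s.n_timepoints for s in self.subjects}) == 1

    def require_equal_length(self, why: str) -> None:
        if not self.equal_length():
            raise ValueError(f"{why} requires equal T across subjects")

    def data_list(self) -> list[np.ndarray]:
        return [s.data for s in self.subjects]

    def subset(self, idx: Sequence[int]) -> "Dataset":
        labels = None if self.labels is None else self.labels[list(idx)]
        return Dataset([self.subjects[i] for i in idx], labels)


@dataclass
class ConnectivityMatrix:
    """A weighted adjacency matrix with method + parameter provenance.

    ``node_semantics`` distinguishes ordinary ROI-level networks from the
    K x K edge-cluster networks produced by dHOFC.
    """

    values: np.ndarray
    method: str = "PC"
    params: dict = field(default_factory=dict)
    node_semantics: str = "roi"  # "roi" | "edge_cluster"
    extras: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in connectivity matrix")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def is_symmetric(self, tol: float = 1e-10) -> bool:
        return bool(np.max(np.abs(self.values - self.values.T), initial=0.0) <= tol)


def symmetrize(W: np.ndarray) -> np.ndarray:
    """W <- (W + W') / 2, the symmetrization used by every constructor."""
    return (W + W.T) / 2.0


@dataclass
class RunConfig:
    """Full configuration of a classification run."""

    method: str = "PC"
    feature_type: str = "edge_weights"  # "edge_weights" | "clustering_coeff"
    selection: str = "ttest"  # "ttest" | "lasso" | "ttest_then_lasso" | "none"
    alpha_ttest: float = 0.05
    lambda_lasso: float = 0.05
    svm_C: float = 1.0
    cv_scheme: str = "loocv"  # "loocv" | "kfold" | "leave_group_out"
    k_folds: int = 10
    repeats: int = 10
    seed: int = 0
    parameter_grid: dict = field(default_factory=dict)
    window_step: int = 1
    inner_cv: str = "loocv"  # inner scheme for nested CV: "loocv" | "kfold"
    inner_k_folds: int = 10
    strict_fold_networks: bool = False
    output_dir: str = "."

    def __post_init__(self) -> None:
        self.method = canonical_method(self.method)
        if self.feature_type not in ("edge_weights", "clustering_coeff"):
            raise ValueError(f"unknown feature_type {self.feature_type!r}")
        if self.selection not in ("ttest", "lasso", "ttest_then_lasso", "none"):
            raise ValueError(f"unknown selection {self.selection!r}")
        if not 0 < self.alpha_ttest <= 1:
            raise ValueError("alpha_ttest must lie in (0, 1]")
        if self.svm_C <= 0:
            raise ValueError("svm_C must be positive")
        if self.cv_scheme not in ("loocv", "kfold", "leave_group_out"):
            raise ValueError(f"unknown cv_scheme {self.cv_scheme!r}")
        if self.method in TYPE_II_METHODS and self.parameter_grid is not None:
            for key, vals in self.parameter_grid.items():
                if len(list(vals)) == 0:
                    raise ValueError(f"empty parameter grid for {key!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["parameter_grid"] = {k: list(v) for k, v in self.parameter_grid.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        return cls(**dict(d))


@dataclass
class LogRecord:
    """Everything a run reports: configuration, suggested parameters,
    selection occurrences and the full metric battery.

    Serializes to a human-readable text log and a JSON document; the JSON
    round-trips losslessly through :meth:`from_json`.
    """

    config: dict
    metrics: dict = field(default_factory=dict)
    suggested_params: dict | None = None
    selection_occurrence: list | None = None  # [(combo dict, count), ...]
    sensitivity: list | None = None  # [(combo dict, accuracy), ...]
    outputs: dict = field(default_factory=dict)  # name -> file path
    software_version: str = ""
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LogRecord":
        return cls(**json.loads(text))

    def to_text(self) -> str:
        lines = ["=== connclass run log ==="]
        if self.timestamp:
            lines.append(f"timestamp: {self.timestamp}")
        if self.software_version:
            lines.append(f"software version: {self.software_version}")
        lines.append("--- configuration ---")
        for k, v in sorted(self.config.items()):
            lines.append(f"{k}: {v}")
        if self.metrics:
            lines.append("--- performance ---")
            for k, v in sorted(self.metrics.items()):
                lines.append(f"{k}: {v}")
        if self.suggested_params is not None:
            lines.append(f"suggested parameters: {self.suggested_params}")
        if self.selection_occurrence is not None:
            lines.append("--- parameter selection occurrence ---")
            for combo, count in self.selection_occurrence:
                lines.append(f"{combo}: {count}")
        if self.sensitivity is not None:
            lines.append("--- parameter sensitivity (LOOCV accuracy) ---")
            for combo, acc in self.sensitivity:
                lines.append(f"{combo}: {acc}")
        if self.outputs:
            lines.append("--- output files ---")
            for k, v in sorted(self.outputs.items()):
                lines.append(f"{k}: {v}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _split_line(line: str) -> list[str]:
    if "," in line:
        return [tok.strip() for tok in line.split(",") if tok.strip() != ""]
    if "\t" in line:
        return [tok.strip() for tok in line.split("\t") if tok.strip() != ""]
    return line.split()


def _parse_table(path: Path) -> np.ndarray:
    """Parse one delimited numeric table; auto-detect delimiter and an
    optional single header row; report the offending file/row/column on
    a non-numeric cell."""
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty file")
    start = 0
    first = _split_line(lines[0])
    if any(not _NUM_RE.match(tok) for tok in first):
        start = 1  # header row of ROI names
        if len(lines) == 1:
            raise ValueError(f"{path}: no numeric rows")
    rows: list[list[float]] = []
    width: int | None = None
    for r, ln in enumerate(lines[start:], start=start + 1):
        toks = _split_line(ln)
        if width is None:
            width = len(toks)
        elif len(toks) != width:
            raise ValueError(
                f"{path}: row {r} has {len(toks)} columns, expected {width}"
            )
        vals = []
        for c, tok in enumerate(toks, start=1):
            try:
                vals.append(float(tok))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {r}, column {c}: {tok!r}"
                ) from None
        rows.append(vals)
    return np.asarray(rows, dtype=float)


def read_time_series(paths: Iterable[str | Path]) -> Dataset:
    """Read per-subject ``T x N`` tables into a :class:`Dataset`.

    Subjects are ordered lexicographically by file path (the label file is
    assumed to follow the same order).  Delimiter and a single header row
    are auto-detected; a consistent ROI count is enforced across files.
    """
    paths = sorted(Path(p) for p in paths)
    if not paths:
        raise ValueError("no input files")
    subjects = []
    for p in paths:
        data = _parse_table(p)
        subjects.append(SubjectTimeSeries(subject_id=p.stem, data=data))
    ns = {s.subject_id: s.n_rois for s in subjects}
    if len(set(ns.values())) > 1:
        raise ValueError(f"inconsistent ROI counts across subjects: {ns}")
    return Dataset(subjects)


def read_labels(path: str | Path, n_expected: int) -> np.ndarray:
    """Read a label file (one +1/-1 per line) of exactly ``n_expected`` lines."""
    path = Path(path)
    vals = []
    for r, ln in enumerate(path.read_text().splitlines(), start=1):
        ln = ln.strip()
        if ln == "":
            continue
        try:
            v = int(float(ln))
        except ValueError:
            raise ValueError(f"{path}: non-integer label at line {r}: {ln!r}") from None
        if v not in (1, -1) or float(ln) != v:
            raise ValueError(
                f"{path}: label at line {r} must be +1 or -1, got {ln!r}"
            )
        vals.append(v)
    if len(vals) != n_expected:
        raise ValueError(f"{path}: expected {n_expected} labels, found {len(vals)}")
    labels = np.asarray(vals, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required (+1 and -1)")
    return labels


def write_time_series(X: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(X, dtype=float), fmt="%.17g", delimiter=",")


def write_network(W: ConnectivityMatrix, path: str | Path) -> None:
    """Write a network as a delimited text matrix plus a JSON sidecar
    (``<path>.meta.json``) holding method/parameter provenance."""
    path = Path(path)
    np.savetxt(path, W.values, fmt="%.17g", delimiter="\t")
    meta = {
        "method": W.method,
        "params": {k: v for k, v in W.params.items()},
        "node_semantics": W.node_semantics,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )


def read_network(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    values = _parse_table(path)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: network matrix must be square, got {values.shape}")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    method, params, semantics = "PC", {}, "roi"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        method = meta.get("method", "PC")
        params = meta.get("params", {})
        semantics = meta.get("node_semantics", "roi")
    return ConnectivityMatrix(values, method=method, params=params, node_semantics=semantics)


# ---------------------------------------------------------------------------
# Memory estimate
# ---------------------------------------------------------------------------


def estimate_memory(
    M: int,
    N: int,
    T: int,
    method: str,
    L: int | None = None,
    s: int = 1,
) -> int:
    """Closed-form estimate (bytes) of the dominant arrays of a run.

    The estimate counts 8-byte doubles for:

    * the cohort itself, ``M * T * N``;
    * one network per subject, ``M * N**2``;
    * pairwise methods: three ``N x N`` scratch matrices;
    * dHOFC: the windowed edge series, ``2 * M * Theta * N(N-1)/2``
      (per-subject series plus the pooled clustering feature matrix),
      with ``Theta = floor((T - L)/s) + 1`` and ``L`` defaulting to
      ``min(50, T - 1)``;
    * SR-family: the stacked dictionaries plus solver workspace,
      ``M * N**2 + 6 * N**2``, and for the group methods (GSR, SSGSR)
      additionally the ``N`` per-ROI ``M x M`` similarity/Laplacian
      matrices.

    It is monotone in each argument and informational only — it never
    blocks a run.
    """
    method = canonical_method(method)
    B = 8
    base = B * (M * T * N + M * N * N)
    if method in ("PC", "tHOFC", "aHOFC"):
        return base + B * 3 * N * N
    if method == "dHOFC":
        L_eff = min(50, T - 1) if L is None else L
        theta = (T - L_eff) // max(s, 1) + 1
        P = N * (N - 1) // 2
        return base + B * 3 * N * N + B * 2 * M * theta * P
    extra = B * (M * N * N + 6 * N * N)
    if method in ("GSR", "SSGSR"):
        extra += B * N * M * M
    return base + extra
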