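# Methods

This note documents the models, the numerical choices, and what the
synthetic cohorts do and do not establish.

## Data model and conventions

A subject is a `T x N` matrix of region-averaged rs-fMRI signals;
labels are `+1` (patient) / `-1` (control) and the positive class
drives sensitivity and precision. Subjects are ordered
lexicographically by file name and the label file is assumed to follow
that order. Input tables may be comma-, tab- or whitespace-delimited
with an optional single header row (detected by a non-numeric first
line). Constant signal columns are flagged at load and their
correlations are defined as 0 rather than NaN, so downstream matrices
stay finite.

Every constructor returns a symmetric matrix; the asymmetric estimators
(aHOFC and the whole sparse family) are symmetrized by
`W <- (W + W')/2`. The sign-geometric-mean alternative
(`sign(w_ij w_ji) * sqrt(w_ij w_ji)`) is deliberately not implemented.
Diagonals of correlation networks are set to 1 by convention (aHOFC's
computed self-connections are overwritten); diagonals are never used as
features, so this is cosmetic. Edge vectorization is the upper triangle
in `(i, j), i < j` lexicographic order.

## Correlation-based estimators

tHOFC/aHOFC profile correlations exclude *both* indices of the pair
(`k != i, j`), so profiles have length `N - 2`. A consequence worth
knowing: on structureless data the fluctuation scale of these profile
correlations is `~(N - 2)^(-1/2)` — they concentrate near zero in the
number of ROIs, not in `T`.

dHOFC uses rectangular windows (no tapering): window `theta` (1-based)
covers rows `[(theta-1)s + 1, (theta-1)s + L]`, giving
`Theta = floor((T - L)/s) + 1` windows; `L = T` is allowed and
reproduces the static PC network in a single window. Edge series are
z-scored per subject, concatenated across subjects, and clustered by
k-means (squared Euclidean, 10 restarts, seeded). Concatenation rather
than cross-subject averaging was chosen so that subject-specific
dynamics still contribute to the metric; the assignment is shared by
all subjects, and the `K x K` network correlates cluster-mean series.
The default window step is `s = 1`, configurable.

## Sparse-representation estimators

All sparse solvers operate on column-standardized signals (zero mean,
unit l2 norm) — recorded in provenance, and invisible to correlation
structure. The diagonal is structurally zero: ROI `i`'s column is
removed from its own dictionary, otherwise `W = I` would minimize every
loss.

Penalty preparation follows the strength-based rules: `sigma` is the
mean over subjects of the standard deviation of off-diagonal `|PC|`
entries (the phrase defining it is ambiguous; this literal reading is
implemented and the value is configurable); link weights are
`C_ij = exp(-FC_ij^2 / sigma)`; WSGR groups edges into `G = 10`
equal-frequency bins of cohort-mean `|PC|` strength with weights
`d_g = exp(-E_g^2 / sigma)` (the original grouping rule is unspecified;
quantile bins are deterministic and scale-free). SSGSR's weights
`b_ij^m = exp(-(w_ij^m)^2)` and per-ROI subject-similarity Laplacians
`L_i = D_i - S_i`, `s_i^{ml} = exp(-||w_i.^m - w_i.^l||^2)` are computed
from all subjects' PC networks; labels are never an input to any
constructor.

**Solvers.** Single-subject and group problems use FISTA with the step
fixed at the reciprocal of the exact Lipschitz constant
(`||D'D||_2`, plus `2*lam2*||L_i||_2` for SSGSR) and function-value
restart. Convergence is declared when the prox-gradient fixed-point
residual `max|w - prox(w - grad/L)| * L` falls below 1e-6 (cap 2000
iterations; a warning plus certificate records non-convergence). The
sparse-group prox is the exact composition soft-threshold-then-group-
shrinkage; SSGSR's row prox with entrywise weights has no closed form
and is solved per row by bracketed scalar root-finding on the
`||diag(b) u||` fixed point (machine-precision bracketing, so the prox
is exact to rounding). The Laplacian term is smooth and lives in the
gradient.

SLR is solved by ADMM with two splitting variables (l1 + zero-diagonal
indicator; nuclear norm via singular-value thresholding), `rho = 1`,
stopping at primal and dual residuals below 1e-6. The reported matrix
is the l1 block (exact zeros, exact zero diagonal). Note SLR's loss
carries no 1/2 factor, so `SLR(lam1, lam2=0)` equals `SR(lam1/2)`; the
cross-method scaling matters when comparing grids.

`lambda_max` helpers give the exact thresholds above which solutions
are identically zero (`max_i ||X_{-i}' x_i||_inf` for l1;
the row-stacked l2 analogue for l2,1).

## Classification pipeline

Per fold: slice per-subject networks -> features (edge weights, or
weighted local clustering coefficients: Onnela-style cube-root triple
products on `|W|` after max-normalization, with `|.|` for negative
weights — zeroing negatives is available via config) -> selection fit
on the training fold -> standardize with training statistics -> linear
SVM (`C = 1`) -> score held-out subjects at threshold 0 (`score >= 0`
predicts +1). Selection is Student's pooled-variance t-test (Welch via
config), LASSO on standardized features under the mean-squared-error
convention (`min 1/(2M)||y - Zw||^2 + lam||w||_1`, so `lam` is
comparable across fold sizes), or their composition; an empty selection
falls back (LASSO -> t-test survivors -> all features) with a logged
warning. A grid value that zeroes every network degrades to a
majority-class rule at chance rather than aborting the run.

LOOCV pools the M held-out scores into one report, so the metric
identities (`BAC = (SEN+SPE)/2`, `Youden = SEN+SPE-1`,
`F = 2*prec*SEN/(prec+SEN)`, `ACC = (TP+TN)/M`) hold exactly; repeated
stratified k-fold averages metrics over folds and repetitions, pooling
AUC within a repetition before averaging across repetitions (per-fold
AUC is undefined when a small test fold is single-class). Repetition
`r` is seeded `base_seed + r`; a partition leaving a single-class
training fold is re-drawn with a deterministic seed offset.
Leave-group-out generalizes leave-center-out and pools like LOOCV.

Nested CV enumerates the parameter grid in the user-given order
(ties break to the first maximizer), evaluates each combination
end-to-end by an inner CV (LOOCV by default) confined to the outer
training set, and trains the outer model at the inner winner. Because
construction never reads labels, per-combination networks are built
once from the whole cohort and sliced per fold — this is the default
for the group constructors (GSR, SSGSR) and for dHOFC's edge
clustering as well. A strict mode instead refits those group-level
constructions on training subjects only and maps test subjects by
least squares restricted to the learned support (GSR/SSGSR) or by the
training-fit cluster assignment (dHOFC).

The parameter sensitivity sweep retrains with full LOOCV at every grid
combination; the peak bar is the *suggested parameters*. *Parameter
selection occurrence* counts each combination's inner-CV wins across
outer folds. The two need not coincide; nested-CV accuracy can never
exceed the sensitivity-sweep maximum on the same data (the sweep is
optimistically tuned).

Feature importance is the mean signed SVM weight per original feature
over the folds in which it was selected (never-selected features report
0 under an occurrence-0 mask), plus the selection-occurrence count; for
dHOFC, each cluster's importance can be expanded to an `N x N` matrix
marking its member edges. Group-mean networks average elementwise
within each label group, at the most-frequently-selected grid
combination for nested runs.

Runs log their full configuration, metrics, suggested parameters,
occurrences and output paths to a text log plus a JSON document that
round-trips losslessly; identical config + seed reproduces identical
structured outputs (timestamps excluded). The memory estimate is a
documented closed form over the dominant arrays (cohort, per-subject
networks, dHOFC edge series, solver workspace, group-method
Laplacians); it is informational and never blocks a run.

## Synthetic cohorts

Three seeded generators emulate the input data:

* **Static**: zero-mean multivariate normal draws with unit-diagonal
  block covariance (default 4 modules, within 0.4 / between 0.05);
  patients get `+delta_r` on planted effect edges. Covariances pushed
  outside the PD cone are repaired by eigenvalue clipping at 1e-8
  (warned when material).
* **Dynamic**: a seeded Markov path (geometric dwell times) over
  connectivity states; in state `s` module `s` is strongly coherent
  (r = 0.9) while other switching modules decohere, and one module
  keeps a constant moderate correlation — its edges are the planted
  "static" contrast for dHOFC.
* **Sparse-representation**: proportional ROI pairs
  `x_{2k+1} = c_k x_{2k} + noise` give an exactly representable cohort
  with known support; an optional group shift on pair coefficients
  plants a classification signal carried by the representation weights
  themselves.

Signals are Gaussian without hemodynamic convolution: sufficient for
correlation and sparse-regression structure, which is all the
estimators consume. Real rs-fMRI adds autocorrelation, drift, motion
artifacts and site effects that these cohorts do not model, so green
tests certify the algorithms and the protocol — not clinical effect
sizes. Problem sizes in the test battery (cohorts of 20–60 subjects,
10–20 ROIs, 22–150 time points; 10–20 seeds per stochastic property)
were chosen as the smallest at which the planted structure is
information-theoretically comfortable, keeping the full suite fast.

## Known limitations

* The classifier is a binary linear SVM; no SVR, multi-class, or
  kernel/hyper-parameter search.
* Graph features beyond weighted local clustering coefficients (path
  length, betweenness) are not provided.
* Group-level constructors in default mode share (label-free)
  information across folds, mirroring the original protocol; use
  strict mode for fully fold-contained construction.
* The LOOCV permutation null is dependent across folds; its accuracy
  is noticeably more variable than a binomial draw, which is why the
  leakage check averages several permutations.
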