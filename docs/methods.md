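# Methods

`dnrfc` implements a multi-order functional-connectivity (FC) pipeline for
recognizing delayed neurocognitive recovery (DNR) from resting-state ROI time
series, together with a synthetic cohort generator that stands in for the
unreleased patient scans. This note records the models, the parameter
choices, the numerical decisions, and what the synthetic experiments do and
do not establish.

## Pipeline model

**Low-order dynamic FC.** A subject is a matrix of 90 regional (AAL-90) BOLD
time series with 115 usable timepoints (TR = 3 s). A sliding window of
length w = 90 with step s = 1 produces K = floor((t − w)/s) + 1 = 26
windows; within each window the 90×90 Pearson correlation matrix is
computed. Feature extraction for the low-order network uses the element-wise
average of the K matrices.

**Edge series and high-order FC.** Each ROI pair (p, q), p < q (E = 4005
edges), has an edge time series: its K windowed correlations. The
high-order network measures co-fluctuation between edges — the correlation
between edge time series. The full E×E matrix is redundant and expensive, so
edges are grouped into 300 clusters by k-means (Euclidean, 10 restarts,
fixed seed) on each edge's series concatenated across the *training*
subjects only; the assignment is frozen and applied to every subject. The
high-order network of a subject is the 300×300 correlation matrix of its
cluster-mean edge series. Fitting the clustering on training subjects only
is the conservative choice against test-set leakage; fitting on all subjects
would be defensible too, and makes little difference to the cluster
structure at this scale.

**Graph features.** Correlation matrices become complete weighted undirected
graphs: weight = |correlation|, diagonal zeroed, rescaled so the maximum
off-diagonal weight is 1. Per node we extract the weighted local clustering
coefficient in the geometric-mean (Onnela) triangle form

    c_i = 2 / (|N_i|(|N_i| − 1)) · Σ_{j<h; j,h∈N_i} (w_ij · w_ih · w_jh)^{1/3},

which lies in [0, 1] and measures neighbourhood interconnection. A
"literal" mode computing 2 Σ_j (w_ij)^{1/3} / (|N_i|(|N_i|−1)) — a
weighted-degree surrogate that appears in some formulations — is available
for comparison, but the triangle form is the default because only it is a
clustering coefficient. Absolute values are used because cube roots of
negative products are undefined and anti-correlation is treated as
connection strength. No sparsification threshold is applied. The feature
vector concatenates 90 low-order and 300 high-order coefficients: 390
features per subject.

**Sparse selection and classification.** Two L0-penalized least-squares
problems are solved greedily (orthogonal matching: add the column most
correlated with the residual, refit on the support, stop when the best
candidate's squared-residual reduction falls below the penalty):

* ranking: φ̂ = argmin ‖l − Fφ‖² + η‖φ‖₀ with η = 0.1, labels ±1, features
  z-scored; features ranked by |φ̂| (non-support features follow, by
  residual correlation, then index);
* classification (SRC): β̂ = argmin ‖f − Dβ‖² + γ‖β‖₀ with γ = 0.05, where
  D holds the z-scored training subjects as unit-norm columns; the test
  subject goes to the class c minimizing r_c = ‖f − D δ_c(β̂)‖, ties to the
  majority (non-DNR) class. A continuous score
  (r_non − r_DNR)/(r_non + r_DNR + ε) feeds ROC analysis.

Exact L0 is NP-hard; on orthonormal designs the greedy scheme equals hard
thresholding of Fᵀl and hence the exact solution (verified against
exhaustive support search), and on general tiny designs it is lower-bounded
by the exhaustive optimum in the tests. Inside SRC the coefficients are
constrained nonnegative (NNLS refits, candidates by signed correlation).
This is deliberate: after z-scoring, two classes that differ by a mean shift
are antipodal directions, and signed coding lets wrong-class columns with
negative weights reconstruct a test vector, collapsing the class-restricted
residual rule to chance. Nonnegativity encodes the classifier's similarity
semantics — a training subject only counts as evidence with positive weight.
The feature-ranking solve keeps signed coefficients.

Sequential forward selection seeds the subset with the top 5 ranked features
and tries candidates ranked 6..100 in order, keeping one only when it
strictly improves stratified 10-fold CV accuracy of the SRC classifier (ties
favour the smaller subset). Note the ranking is fit on the full training
split, so the CV metric that guides selection is optimistically biased — the
original procedure shares this property; only the held-out metrics are
honest performance estimates, and on synthetic cohorts the gap between
saturated CV accuracy and held-out accuracy is visible.

**Evaluation.** 2:1 stratified train/test split with largest-remainder
per-class rounding (74 subjects → 49 train / 25 test; remainder ties go to
the larger class, so the test set keeps 6 DNR / 19 non-DNR). DNR labelling
from neuropsychological panels uses the Z-score rule: per test,
Δ = baseline − post-op, Z = (Δ_patient − mean Δ_control)/sd(Δ_control), and
a patient is DNR when Z > 1.96 on ≥ 2 tests; only the decline direction
counts, treating DNR as a decline construct. Screening uses pooled-variance
two-sample t-tests (Welch behind a flag). Unsupervised validation clusters
z-scored selected features with Ward linkage cut at 2 groups and reports the
best label-assignment agreement. AUC is the Mann–Whitney rank statistic with
0.5 tie credit, verified against exhaustive pairwise comparison; ACC/SEN/SPE
use DNR as the positive class.

## Synthetic cohort generator

The generator emulates a 16 DNR / 58 non-DNR cohort of 90-ROI series with
115 usable timepoints. Signals are zero-mean multivariate Gaussian AR(1)
processes (coefficient 0.3) whose innovation correlation is a shared
low-rank "network backbone" (a blend of random loadings with identity,
off-diagonal magnitudes mostly below 0.4). DNR subjects receive an
additional correlation of `effect_size` = 0.4 on `n_effect_edges` = 50
designated weakly-connected ROI pairs — the stronger-connectivity phenotype —
and this increment is modulated blockwise over 3–5 equal-length stationary
segments with relative amplitude `dynamic_effect` = 0.3, giving the DNR
class distinguishable edge *time series* so that high-order features carry
signal. Edited matrices are repaired by alternating projections between the
edge-target constraint and the PSD/unit-diagonal cone; a single projection
would shrink the injected effect by ~15–20%. `noise_sd` = 1 is a pure scale
and does not affect correlations.

What the generator does *not* emulate: hemodynamic response shapes,
scanner drift and motion, spatial (voxel-level) structure, global signal,
physiological noise spectra, or site effects. Passing tests therefore
establish that the pipeline recovers the designed covariance and dynamics
structure at realistic dimensions — not that it would achieve any particular
accuracy on real scans.

The temporal preprocessing (discard 5 volumes, linear detrend, zero-phase
4th-order Butterworth band-pass 0.01–0.08 Hz) follows standard
resting-state practice; the band-pass is applied forward-backward so no
phase is introduced and window alignment is preserved. Whether nuisance
regression precedes or follows filtering is not fixed by the pipeline's
sources; here the order is discard → detrend/filter → covariate regression.

## Numerical choices and degenerate inputs

* Windows are 0-based half-open `[j·s, j·s + w)`; the final partial window
  is discarded (floor in K).
* A ROI constant within a window makes Pearson undefined: error by default,
  optional 1e-10 jitter for degenerate synthetic inputs.
* A constant cluster-mean edge series gets high-order correlations of 0 with
  a warning.
* k-means leaving an empty cluster is retried with a stepped seed (3
  attempts) before raising; `n_clusters` = E degenerates to the identity
  assignment.
* Correlation matrices are symmetrized and clipped to [−1, 1] after
  `corrcoef` to absorb roundoff; symmetry is asserted to 1e-12 in tests.
* Zero-variance feature columns are excluded from L0 solves with a warning;
  zero pooled variance in t-tests yields p = 1 with a warning.
* Split remainder ties: toward the larger class (see above). Equal SRC
  residuals: non-DNR. Ranking ties: ascending feature index.

## Problem sizes used in the checks

The full-scale configuration (74 subjects, 90 ROIs, 115 timepoints, 300
clusters) runs in well under a minute for feature extraction and is used by
the analysis drivers and the acceptance script. The statistical suites use
reduced designs chosen to make their target quantity measurable with stable
Monte-Carlo error: effect-recovery checks use 20–40 ROIs with 8–40 subjects
per class over 20 seeded cohorts; selection-recovery uses 20 replicates of a
90-subject, 390-feature cohort with 5 complementary informative features
(class signal split across them by sum-to-zero anti-correlated noise, so the
subset genuinely needs all 5); null calibration uses 25 label-permuted
reduced cohorts (24 subjects, 20 ROIs, 50 features) for t-test rates and 6
for classifier accuracy.

## Known limitations

* The greedy L0 solver is exact only on (near-)orthogonal designs; at
  n_train ≈ 49 with 390 correlated features its deep support makes the
  |φ̂| ranking unstable, and forward selection inherits that instability.
  This mirrors the small-sample fragility of sparse-representation feature
  selection generally; the univariate t-test ranking is available as a more
  stable screening alternative.
* With a strong synthetic effect the training CV metric saturates at 1.0,
  so forward selection stops early and selected subsets stay small.
* The SRC score is a residual ratio, not a calibrated probability; AUC is
  meaningful, absolute score magnitudes are not.
* The edge clustering is k-means on concatenated training series; other
  groupings (spectral, hierarchical) were not explored.
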