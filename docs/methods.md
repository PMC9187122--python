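# Methods

`phenoclust` identifies subtypes in a cohort of individuals sharing a complex
symptom complex by clustering heterogeneous baseline data: continuous
clinical measurements and questionnaire scores together with binary-expanded
categorical variables (comorbidities, medication use, exam findings), with a
smaller reference group of individuals *without* the condition supplying the
scaling statistics, and an optional extra data domain observed on only part
of the cohort.

## Preprocessing

**Multiple imputation.** Missing values (each column must be under 50%
missing) are completed `n_imputations` times (default 10).  The default
imputer performs two sweeps of chained linear regression for continuous
columns (prediction plus Gaussian noise at the residual SD) and draws
categorical values from the observed empirical distribution, with a
per-imputation RNG stream derived from one seed.  Any external imputer can
be injected through the `method` argument of `impute_multiple`; the
downstream pipeline only requires a list of complete tables.  The
consensus step runs once per completed table and the resulting pairwise
probabilities are averaged.

**Control-referenced scaling.** Each continuous variable is standardized as
`S_in = (A_in − mean_C) / sd_C` using the mean and SD of the *control*
(reference) population, not of the cohort.  Cohort z-scores divide by a
variance that is inflated precisely along subtype-separating variables
(their cohort distribution is multimodal), shrinking the very signal the
clustering needs; control scaling leaves that signal intact while still
removing units.  The transformation is equivariant under rescaling of a raw
variable (controls rescale identically), so cluster solutions cannot depend
on the units a variable happens to be recorded in.

**Redundancy weights.** `w_i = 1/(1 + c_i/c̄)`, where `c_i` is the mean
absolute Pearson correlation of variable `i` with all others and `c̄` the
grand mean over ordered pairs.  Correlations enter in absolute value —
strong negative correlation is redundancy too; the same Pearson/phi
convention is used for 0/1 indicators.  Weights lie in (0, 1]; the least
correlated variable gets the largest weight; if every correlation is zero
all weights degenerate to 1.  Weights are computed once on the first
completed dataset (the `weights_per_imputation` flag recomputes them per
imputation), and separately within the continuous block and the indicator
block, matching how the two channels are assembled below.

**Row normalization.** Each subject's weighted continuous profile is
rescaled to unit Euclidean length (`L_n = sqrt(Σ (w_i S_in)²)`,
`V_in = w_i S_in / L_n`).  Without it, clustering tends to split the cohort
by overall severity; normalizing makes the *direction* of the profile, i.e.
the pattern of symptoms, the clustered quantity.  A subject exactly at the
control means on every variable has no direction and is rejected with its
id named.

**Categorical relevance.** For each binary indicator the case frequency
`F_j` is compared with the control frequency: `γ_j = |ln(F_j/F_jC)|`, with
a pseudo-frequency of `0.5/(n_controls+1)` guarding zero frequencies and a
cap at γ = 6 (erf is ≈1 long before).  The indicator's usable weight is
`erf(γ_j) ≤ 1`, so an indicator far more frequent in cases than controls
still cannot dominate, and one equally frequent in both (γ = 0) drops out
of the distance entirely.

## Clustering

**Consensus k-means (continuous channel).** 1000 random subsamples of 80%
of subjects (without replacement), each partitioned by k-means (k-means++
starts, best of 8 restarts by inertia, 300 iterations max, tol 1e-6 — the
iteration cap and tolerance are this implementation's defaults).  `M_nq =
Q_nq / I_nq` estimates the probability that subjects n and q co-cluster;
per-resample RNG streams are spawned from the master seed up front, so the
matrix is reproducible and independent of execution order.  Pairs never
co-selected (vanishingly rare at these settings) are filled with the grand
mean under a logged warning.  `1 − M` is a distance; membership comes from
cutting an average-linkage tree (complete and Ward available).

**Weighted Tanimoto (categorical channel).** Tanimoto similarity counts
shared ones, never shared zeros, so splitting a categorical variable into
more indicator columns does not dilute similarity.  Each indicator enters
with the factor `w_j²·erf(γ_j)²`.  The distance is `1 − T`.  Two subjects
who are all-zero on the weighted support are treated as identical
(distance 0, logged); the matrix is symmetric with zero diagonal but is not
guaranteed to satisfy the triangle inequality.  The distance is computed per
imputed dataset and averaged, mirroring the consensus averaging.  The
k-prototype centroid distance φ is implemented as a documented reference
operation only; the pipeline does not use it.

**Fusion.** `D_nq = sqrt(((1−M_nq)² + μ²(1−T_nq)²)/(1+μ²))` — a weighted
root-mean-square, which keeps D in [0, 1].  The channel weight μ defaults
to `Σ w_j^cat / Σ w_j^cont`, the ratio of non-redundant categorical to
continuous variable counts, and can be overridden in the config.

**Semi-supervised refinement.** For the subset of subjects with the extra
domain observed, pairwise distances `BD` are recomputed by the same
consensus procedure at the same K on the subset's normalized matrix with
the extra variables appended (scaled by their own control references;
redundancy weights recomputed on the augmented set).  Then
`G_nq = max(D_nq + ρ·(BD_nq − mean BD), 0)` for pairs fully inside the
subset; other pairs keep `D_nq` (their unknown extra-domain distance is
taken equal to the subset mean, zeroing the shift).  The shift is mean-zero
over subset pairs, so refinement redistributes rather than inflates
distance; clipping at zero is counted and reported.

## Model selection and evaluation

**Contrast criterion (CC).** Per cluster: mean within-cluster off-diagonal
similarity minus mean similarity to all other subjects; CC is the
unweighted mean over clusters (size-weighted and minimax variants are
deliberate non-defaults, selectable in code).  Diagonal entries are
excluded — they make up `1/N_k` of a cluster's block (50% for a pair) and
would bias CC toward small clusters.  On consensus-type input CC ranges
from 0 (constant 1/K matrix) to 1 (ideal blocks) irrespective of K, which
is its advantage over the consensus score CS, whose floor 1/K moves with K.
Edge cases are implementation-defined here: a singleton cluster contributes
a within-term of 0, K = 1 gives CC = 0, and K = N gives CC = −mean
off-diagonal similarity.

**Core probabilities and PCC.** `π_nk` is the mean similarity between
subject n and the members of cluster k (divisor `N_k − 1` inside the own
cluster, `N_k` outside).  A core member has `π > 0.5` — more likely in its
cluster than in all others combined; a singleton's own-cluster π is
undefined and counts as non-core.  PCC, the per-cluster core fraction and
its unweighted mean, measures confidence in membership.

**Selection.** The scan runs the full pipeline over K (default 2–12) and ρ
(default 24 values, 0.05–1.2); the selected pair maximizes CC, with ties
broken by larger PCC and then smaller K.  The PCC elbow (largest negative
second difference over K at the selected ρ) is reported alongside rather
than automated into the decision — "point of diminishing returns" is a
judgment call and the full curve is always available.  PAC (fraction of
off-diagonal entries strictly between 0.1 and 0.9), CS, and the CDF
delta-AUC elbow are computed for comparison.

**Evaluation.** Classical indices: Calinski–Harabasz and Davies–Bouldin
(coordinate-based), silhouette (precomputed distance), Dunn (min
between-cluster distance over max diameter), and a point-biserial index
defined here as the point-biserial correlation between pairwise distance
and the same-cluster indicator — good clustering drives it negative, so
lower is better under this sign convention.  Pairwise cluster comparisons
use Wilcoxon rank-sum tests for continuous variables and chi-square tests
for indicators, falling back to Fisher's exact test when any expected cell
count is below 5; Benjamini–Hochberg FDR is applied within each cluster
pair across its variables, and the summary matrix reports the proportion of
significantly different variables per pair.  Longitudinal "improvers" are
subjects whose summary score drops by at least half a baseline SD
(boundary inclusive).

## Synthetic cohorts

The generator plants `K_true` subtypes: continuous variables get
heterogeneous control means (uniform on [−2, 10]) and log-uniform control
SDs (10^[−1, 2]), emulating clinical panels that mix unrelated units; each
cluster shifts its own disjoint subset of the informative half of the
continuous variables by ±`effect_size` control-SDs (disjoint subsets keep
the planted structure identifiable).  Every informative binary indicator
carries a cluster-specific frequency (control frequency ±`cat_effect`,
clipped to [0.02, 0.98]) — subtype profiles differ across the whole
informative panel, as comorbidity patterns do.  Missingness is MCAR only
(`missing_rate`, default 10%); a MAR mechanism is an extension point.
Noise is Gaussian by default with a Student-t option (unit-variance scaled)
for robustness checks.  A random `subset_fraction` of cases carries
`n_subset_vars` extra continuous variables with their own control
references.  Default shape: 545 cases, 55 controls, 78 continuous + 102
binary variables, five subtypes, 35% subset with five extra variables.

What the generator does **not** emulate: realistic item-response
distributions (ordinal scales, floor effects), informative missingness,
correlated noise between variables beyond what the planted structure
induces, and measurement error in the control references.  Passing the
planted-recovery tests therefore shows the pipeline recovers structure of
the *assumed* form at the simulated separation, not that any particular
clinical dataset contains such structure.

Truth-based scoring uses the minimum mismatch over cluster relabelings
(Hungarian assignment on the confusion matrix, rectangular label sets
allowed) plus the adjusted Rand index.

## Validation experiment sizes

The planted-recovery experiment uses 300 cases, 30 continuous + 30 binary
variables, five subtypes at 2 control-SD shifts, 200 resamples on a single
completed dataset (no missingness), K scanned 2–8, ten replicates — a
scaled-down but structurally faithful version of the full default run.  The
scaling-strategy comparison (control-referenced vs cohort z-scores vs raw)
uses 20 replicates of a continuous-only cohort (150 cases, 20 variables,
two subtypes), consensus at the true K with 50 resamples; it reproduces the
expected ordering of mean misclassification: control-scaled ≤ z-scored ≤
raw.  Null calibration of the pairwise tests uses 50 replicates of two
same-distribution clusters of 40 subjects over 20 variables.

## Known limitations

* The weighted Tanimoto distance is not a metric; downstream steps
  (average-linkage trees, CC) do not require the triangle inequality.
* CC's edge-case definitions (singletons, K = 1, K = N) are this package's
  conventions, chosen for continuity, and are flagged as such above.
* The default imputer is a deliberately simple chained scheme intended for
  moderate MCAR missingness; heavier or structured missingness warrants an
  external imputer injected via the pluggable interface.
* With very small subsets (< 2K members) refinement is refused rather than
  attempted.
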