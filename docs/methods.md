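# Methods

This note documents the statistical procedures, the synthetic-data
generator's assumptions, the numerical choices, and the limitations of both.
It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Sensory model

Ratings arrive in long format (panelist × sample × attribute). Hedonic
attributes (liking, texture liking) live on a bipolar [−100, +100] scale;
intensity attributes (sweetness, sourness, flavor intensity) on [0, +100].
Panelists differ systematically in scale use, so per-sample means are
adjusted with a mixed linear model per attribute:

    score_ij = mu_i + b_j + e_ij,   b_j ~ N(0, sigma_p^2),  e_ij ~ N(0, sigma_e^2)

with sample `i` fixed and panelist `j` a random intercept. The REML
criterion is profiled analytically over the fixed effects and sigma_e^2,
leaving a one-dimensional maximization over the variance ratio
theta = sigma_p^2 / sigma_e^2, solved by a bracketing grid plus golden
section to a relative tolerance of 1e-8. Because panelists rate only the
samples of their session, the mixed-model equations are block-diagonal over
connected components of the sample–panelist graph; each component is solved
through a Schur complement on its sample effects, so fits with thousands of
panelists take milliseconds. Sessions are treated as independent blocks with
no session fixed effect. A design in which every panelist rates a single
sample is rejected as non-estimable; samples rated once are flagged and
keep their (high-SE) mean.

Attribute structure is summarized with Spearman rank correlations across
sample means (a record-level option is deliberately not provided: the
adjusted means are the quantity the rest of the pipeline consumes), and
partial correlations controlling sweetness are computed on ranks with the
first-order formula r_xy.z = (r_xy − r_xz r_yz)/sqrt((1−r_xz²)(1−r_yz²)),
keeping them Spearman-consistent. Temperature trends are ordinary least
squares of a response on the 5-day mean soil temperature, pooled and per
genotype; a genotype with a single covariate value is an error, not a NaN.

## Chemical harmonization

Quantification campaigns in different periods shift abundances
systematically, so each compound is autoscaled (z-scored) within each
period, using the sample standard deviation (n−1). Values missing at the
sample level are excluded from the mean/SD and can either stay missing or be
imputed at the period's minimum z-score (`impute="min_z"`) — the package's
reading of "present but near the floor". Compounds constant or detected
fewer than twice within a period are dropped from that period with a
warning, never silently. An optional log transform before scaling
(`log_transform=True`, the pipeline default) linearizes the multiplicative
abundance structure; raw-scale autoscaling remains available and is the
function's default. Period merging keeps compounds detected in every period
(`common`) or any period (`union`) and reports the retained classes.

## Correlations, network, cluster support

All-pairs Pearson correlations are computed on pairwise-complete samples
(pairs with fewer than 5 shared samples are excluded and logged), with
two-sided p-values and both Benjamini–Hochberg and Bonferroni columns; the
default significance count is adjusted p < 0.01. The network keeps pairs
surviving Bonferroni at alpha = 0.05 (both the adjustment column and alpha
are parameters), weights edges by |r|, and scores nodes by authority
centrality. For an undirected graph the authority vector of A'A coincides
with A's Perron eigenvector; power iteration runs on A plus a positive
spectral shift (1 + max row sum) because the unshifted A² iteration is
degenerate on bipartite-like components (on a 3-node path the all-ones
start is itself an A² eigenvector). Components are solved independently,
weighted by their Perron value, and the final scores are max-normalized.
No alpha for the network filter is claimed to reproduce any particular
published edge count; the choice is documented, not fitted.

Hierarchical clustering uses 1 − Pearson r between variables and legacy
Ward linkage ("ward.D"): SciPy's Ward recurrence operates on squared input
distances, so the implementation feeds it sqrt(d) and squares the merge
heights. Cluster support follows the multiscale bootstrap: at each scale
r ∈ {0.5, …, 1.4} (10 values; the grid must straddle 1), n·r samples are
resampled with replacement n_boot times (default 1000) and each base
cluster's appearance frequency BP_r is recorded. The approximately unbiased
p-value comes from the signed-distance/curvature fit: z_r = Phi⁻¹(1 − BP_r)
is regressed on (sqrt(r), 1/sqrt(r)) by weighted least squares with
binomial-variance weights, and AU = 1 − Phi(v − c). Frequencies of exactly
0 or 1 are clipped at half a count; clusters with fewer than two informative
scales fall back to their plain BP. The root reports AU = BP = 1.

## PLS–VIP selection

Per period, the sensory response (standardized within period; VIP and R²
are invariant to this) is regressed on that period's detected compounds
plus standardized texture liking, with a 3-component NIPALS PLS (weights
from X'y, score/loading updates, deflation of X and y). Requesting more
components than the predictor rank, or exhausting the residual covariance,
raises a component-limit error. VIP uses Wold's formula with the component
y-sum-of-squares SS_a = q_a² t_a't_a; the identity Σ_j VIP_j² = p holds to
machine precision and is asserted in tests.

A volatile is a consensus candidate if VIP > 1.0 in at least 2 periods;
periods where it was undetected cast no vote. Candidates then face a
two-sided t-test on their slope in `response ~ volatile + total_sugars`
(total sugars = glucose + fructose + sucrose per sample), Bonferroni
over the candidates actually tested for that response — not over all
volatiles — because that is the family actually inspected. A volatile
correlated with total sugars beyond |r| > 0.999 is reported
non-identifiable rather than tested. Sugars, acids and texture liking
participate in the PLS but never appear in the selection report.

## Predictive benchmark

Each of 100 iterations draws one random 90/10 split shared by every
algorithm (paired comparisons; the per-iteration test-index hash is stored
and asserted). Inside the 90 %, hyperparameters are tuned by 5-fold CV:
lasso (alpha grid 0.01–0.3), componentwise L2-boosting (steps 100/300,
shrinkage 0.1; each step refits every single predictor to the residual and
adds a shrunken copy of the best), random forest (200 trees, max-features
grid), PLS (2/3/5 components); OLS and Bayesian ridge have nothing to tune.
The nested-CV R² pools the inner-fold predictions per iteration; the test
R² is 1 − SS_res/SS_tot with SS_tot centered on the evaluation fold's own
mean (training-mean centering is a config switch). The baseline is OLS on
exactly sucrose, glucose, fructose, malic and citric acid under the same
splits; passing any other feature set to the baseline is an error. With
10 % test folds of ~15 samples the fold-centered R² estimator is biased
downward by several points; recovery tests of planted variance fractions
therefore run at larger n where the bias is negligible. Degenerate test
folds (constant response) are skipped with a log entry.

## Genetics

Phenotypes (right-skewed volatile abundances) are Box-Cox transformed with
lambda maximizing the profile log-likelihood (scipy's boxcox_llf) over
[−2, 2] by bounded scalar minimization (xatol 1e-6); non-positive values
are a domain error naming the sample. The association scan is the plain
single-marker analysis: OLS of the normalized phenotype on additive dosage
per marker with casewise deletion of missing calls, R² = model SS/total SS
(equal to the squared dosage–phenotype correlation), F-test p-values and
BH-FDR across markers. No kinship or structure correction is attempted —
that is a deliberate scope boundary, since the package emulates a single
population at a time. Genotype-class reports give per-class means with
Tukey-HSD compact-letter groupings at alpha 0.05 (greedy letter
insertion). PCA centers (and for chemical matrices optionally autoscales)
the data after omitting any variable with missing values, and reports
percent variance summing to 100.

## The synthetic generator

The generator emulates the study conditions the analyses assume; defaults
are chosen once and the truth registry records every planted parameter.

* **Design**: 148 samples in 3 contiguous periods; sessions of 4 samples
  with 100 panelists each; 48 genotype labels; 113 volatiles of which 59
  are detected in all periods (the remainder get random proper subsets);
  sugars (glucose, fructose, sucrose) and acids (citric, malic) always
  measured.
* **Abundances** are log-normal: base level + pathway-factor loading
  (U(0.6, 1.0) on one of 8 latent pathways — producing correlated
  ester/aldehyde blocks) + period offset (N(0, 0.5) in log units) +
  biological noise (U(0.3, 0.6)) + technical noise (0.15, shrunk by
  averaging over 3 replicates). This yields ≥ 70-fold abundance ranges for
  many volatiles. Sample-level nondetects are censored 2.5 SD below a
  compound's mean. Glucose and fructose share a factor tuned to r = 0.91
  on the batch-free log scale (the raw correlation is diluted by period
  offsets and is recovered after autoscaling).
* **Sensory truth**: sweetness = intercept 40 + sugar driver + enhancer
  effects + optional temperature trend + residual, with a total
  sample-level SD of 18 rating units. The sugar driver is the standardized
  mean of the three log sugar signals — linear in the measured (log)
  sugars, so the planted fraction (default 40 %, matching a sugars+acids
  baseline around R² 0.4) is recoverable by regression. Each of the 3
  enhancers acts on the standardized batch-free log abundance with a slope
  worth 12 % of sweetness variance; jointly ~36 %, consistent with
  benchmark studies where volatile-aware models add ~25–30 points of R²
  over sugars. Enhancers are drawn from the always-detected set and get
  dedicated latent factors: their effect is compound-specific, not a
  pathway proxy — otherwise every pathway-mate would be a legitimate
  correlated hit and a "≤ 1 false positive" recovery criterion would be
  meaningless. Liking shares the enhancers, takes 0.75× the sugar
  fraction, and adds a component shared with the sweetness residual;
  sourness follows acids; panels add N(0, 10²) panelist offsets and
  N(0, 15²) rating noise, then clip to the scales (the clipped fraction is
  exposed via `clipping_fraction`).
* **Genotypes**: biallelic markers under Hardy–Weinberg; the QTL marker's
  additive effect a satisfies 2p(1−p)a² = q on the unit-variance log
  scale (q = 0.15 by default at allele frequency 0.3), and the phenotype
  is exponentiated so Box-Cox (λ ≈ 0) must undo the skew before the scan.
* **Reproducibility**: one seed feeds named substreams (truth, chemistry,
  sensory, genotypes), so adding a generator never shifts another's draws
  and identical configs are bitwise identical.

What the generator does **not** emulate: GC peak shapes or retention
times, panelist demographics or serving order, genotype-by-environment
interaction beyond a linear temperature term, kinship structure among the
genotyped individuals, and non-Gaussian rating distributions beyond
clipping. Passing recovery tests therefore shows the procedures are
correct and well-powered under these assumptions, not that any particular
real study satisfies them.

## Problem sizes in tests and the acceptance script

Recovery and calibration checks use the study-scale defaults (n = 148,
50 replicates for enhancer recovery, 20 for null calibration, 50 × n = 300
for QTL recovery); the benchmark's planted-variance checks use n = 600 so
the fold-centered R² estimator's small-sample bias does not contaminate
the comparison; the pipeline smoke tests use miniature studies (20–60
samples) since they exercise plumbing, not power. The acceptance script
runs the full chain at defaults with 10 recovery replicates, 25 QTL
replicates and a 20-iteration lasso benchmark.

## Known limitations

* The AU p-value fit clips degenerate bootstrap frequencies; clusters that
  appear in essentially every or no resample carry AU values driven by the
  clipping constant (as in the reference multiscale-bootstrap tooling).
* The sugar-independence test conditions on total sugars only; a volatile
  correlated with acids or texture can still owe part of its slope to
  them.
* Authority centrality on components whose Perron value ties is reported
  in node-id order; exact ties are broken deterministically but
  arbitrarily.
* The benchmark's hyperparameter grids are small by design; they bound the
  tuning cost and are documented, but a practitioner may wish to widen
  them for real data.
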