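# Methods

This note documents the statistical machinery in `markerpipe`: the models,
their assumptions, the defaults that matter, and the numerical choices made
where the design was genuinely open. No empirical claim here goes beyond
what the test suite and `scripts/acceptance.py` themselves compute.

## Preprocessing

**Imputation.** Local least squares (default): for each incomplete variable,
the `k = 10` complete variables most similar to it — similarity is absolute
Pearson correlation over the shared observed samples — form the predictors
of an ordinary least-squares regression (with intercept) fit on the target's
observed samples; missing entries are predicted from that fit. When fewer
than `k` eligible neighbours exist the variable falls back to its observed
mean, with a warning; a fully missing variable is an error because nothing
identifies it. k-NN imputation averages the `k` nearest variables' values at
the missing sample, with Euclidean distance over shared observed
coordinates. Observed cells are never altered, and for targets that are
exact linear combinations of `k` complete variables LLS recovery is exact to
numerical precision (a tested invariant). `k = 10` is the conventional
default for expression-scale data; both methods assume missingness is
unrelated to the unobserved values (MCAR/MAR), which is also all the
synthetic generator produces.

**Low-count filter.** A count variable is kept iff CPM > 1 in at least `m`
samples, `m` being the smallest group size — the standard concretization of
"filter low counts over all groups" that cannot silently delete a variable
expressed only in the smallest group.

**TMM.** The reference sample is the column whose upper-quartile CPM is
closest to the mean upper-quartile. For each sample, M (log2 ratio) and A
(mean log2 abundance) are computed on the CPM scale over variables positive
in both sample and reference; 30% of M (15% per tail) and 5% of A (2.5% per
tail) are trimmed and the surviving intersection is averaged with inverse
delta-method binomial variances as weights; the factor is 2^(weighted mean).
Factors are rescaled to geometric mean 1. The variance weights are computed
on the CPM scale (nominal library 10⁶) so that rescaling any column — a pure
sequencing-depth change — leaves factors exactly unchanged; raw-count
weights would break that invariance in the fourth decimal.

**Precision weights for counts.** log2-CPM uses pseudocounts 0.5 on the
count and 1 on the effective library size:
`log2((y + 0.5) / (N·f + 1) · 1e6)`. Per-variable residual standard
deviations under the model design are lowess-smoothed (span 0.5) on the
sqrt scale against mean log2-CPM; each observation's weight is
trend(fitted value)⁻⁴. The sqrt-sd is floored at 1e-4 before the
fourth-power inversion so zero-variance variables cannot produce infinite
weights. When the trend is flat all weights coincide, so the weighted fit
degenerates to OLS — the correct limit.

**Continuous normalization.** log2/log10 (optional +1 offset) or logit
transforms, then quantile normalization (each column's order statistics are
replaced by the across-column means; a tied block receives the mean of the
reference values its ranks span, which keeps output deterministic) or
mean/median centering.

## Distributional diagnostics

Sample skewness m₃/m₂^1.5 and raw kurtosis m₄/m₂² (n denominators; normal
reference 3, matching Cullen–Frey axes — stated here to avoid raw/excess
confusion). Candidate distributions are fit by maximum likelihood: normal,
lognormal, Poisson, and binomial in closed form (binomial success
probability with size fixed at the sample maximum, since joint ML over both
parameters is ill-posed on small samples), gamma and Weibull numerically
with location pinned at zero. Candidates whose support the data violate are
skipped with a reason, not failed. The bootstrap cloud resamples n values
with replacement per replicate (default 500, seeded; constant resamples are
redrawn up to 100 times). Ten randomly selected variables are inspected per
run. Interpretation is left to the user; nothing is auto-rejected.

## Clustering

K-means is Lloyd iteration, best of 25 seeded restarts by within-cluster sum
of squares; an emptied cluster is re-seeded at the point farthest from its
centroid. The number of clusters is scanned over 2..min(10, n/3) and scored
by the BIC of a spherical equal-variance Gaussian mixture evaluated at the
k-means partition (parameter count k·d + k − 1 + 1); ties go to the smaller
k. This is the minimal mixture family consistent with k-means geometry — a
full covariance-family EM search is deliberately out of scope. Sample maps
use classical (Torgerson) MDS on Euclidean distances over the 500 most
variable variables; exactly collinear configurations embed on one axis with
the second coordinate zero.

## Differential expression

Each variable is fit by least squares under a shared design: intercept,
treatment-coded group dummies, optional batch dummies (batch correction is
inclusion in the design, not data editing), and numeric covariates.
Rank-deficient designs are rejected naming the aliased columns. With count
data the voom weights enter as per-observation WLS. All pairwise group
contrasts are generated for multi-level factors.

Residual variances are shrunk toward a scaled inverse-chi-square prior. On
the log scale, E[log s²] and Var[log s²] have closed forms in digamma and
trigamma; matching the empirical moments gives d₀ (via Newton inversion of
the trigamma) and s₀². When the observed spread of log s² does not exceed
pure sampling noise, d₀ = ∞ and every posterior variance collapses to s₀²
(flagged). The moderated t uses s̃² = (d₀s₀² + d·s²)/(d₀ + d) on d₀ + d
degrees of freedom (normal in the infinite-d₀ limit). The prior is constant
— no variance trend — because the precision weights already absorb the
count mean–variance relationship. Multiple testing is Benjamini–Hochberg
step-up. Significance calls use strict inequalities (FDR < cut,
|log₂FC| > cut), so a variable exactly at a threshold is excluded.

## Penalized selection

The elastic net minimizes −(1/n)·loglik + λ(α‖β‖₁ + (1−α)/2·‖β‖₂²) for
logistic (two groups) or symmetric multinomial (three or more) likelihoods,
by cyclic coordinate descent inside an IRLS loop: predictors are
standardized internally, λ runs down a 100-point log grid spanning four
decades from λ_max (the smallest λ with an empty model), with warm starts;
an active-set strategy with a vectorized KKT screen keeps each step cheap.
IRLS weights are floored at 1e-5 to keep the quadratic approximation
bounded on separable data.

Protocol defaults mirror the screening design: α = 0.5, 10-fold stratified
CV, λ chosen at the CV minimum (the 1-se rule is available but the minimum
maximizes selection sensitivity, which fits a screening tool), automatic
2:1 stratified train/test split when the smallest group has ≥ 15 samples
(below that the data are too small to give away a third, and results serve
only as support for the moderated-t calls), test AUC by the Mann–Whitney
statistic with midrank ties (macro one-vs-rest for multinomial). The run is
repeated 10 times with seeds base+r, re-randomizing folds and split; the
selection set is the variables chosen in at least half the runs (majority
vote), and the consensus table intersects it with the DE calls.

## Co-expression

Unsigned adjacency a_ij = |cor(x_i, x_j)|^β with zero diagonal. β is the
smallest integer in 1..20 whose connectivity distribution reaches signed
scale-free R² ≥ 0.8 (log-log regression over 10 connectivity bins; the sign
convention makes only decreasing fits count), else the best-fitting power
with a warning. Topological overlap
w_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij) with l = A²; modules come
from average-linkage clustering of 1 − w with a static cut at height 0.99
and a minimum size of 20 (smaller branches are unassigned, label 0); the
static cut is deterministic and fully specifiable, with dynamic tree cutting
noted as an extension. Module eigengenes are first principal components of
the standardized blocks (unit norm, sign anchored to positive mean
loading); module pairs with eigengene dissimilarity 1 − cor < 0.25 are
merged iteratively, closest first, recomputing eigengenes after each merge.
Intramodular connectivity kWithin_i sums a variable's adjacency to its
module; each module reports its top ceil(0.25·size) hub variables. Above
5000 variables the network is built block-wise (k-means pre-clustering of
profiles into blocks ≤ 5000, per-block detection, cross-block eigengene
merge). The paired screen computes per-variable Spearman correlation
(Pearson on midranks) between two sample-paired matrices, p from the
t-approximation on n − 2 df, BH across variables, and a one-sided gate
ρ > 0.5 with FDR < 0.05; variables with fewer than 4 complete pairs are
flagged untestable.

## Survival screening

Cox partial likelihood with Efron tie handling, maximized by Newton–Raphson
with step halving (score-norm tolerance 1e-9, max 100 iterations). Efron is
preferred to Breslow because it is the better approximation under ties at
no extra cost. Monotone likelihoods (separation) are detected as diverging
estimates (|β| > 15) and flagged non-estimable rather than raised; such
variables are excluded from the FDR computation.

Assumption checks run on the adjustment covariates before screening.
Proportional hazards: a correlation-type score test of the scaled
Schoenfeld residuals (d·V⁻¹s_k + β̂) against the Kaplan–Meier transform of
event time (1 − left-continuous KM), χ² with 1 df per covariate — the
standard Grambsch–Therneau construction. Linearity (continuous covariates
only): likelihood-ratio test of the linear entry against a 3-column natural
cubic spline basis with interior knots at the 25th/75th percentiles and
boundary knots at the range (χ², 2 df). A covariate failing linearity at
α = 0.05 enters all screening models through its spline basis. Each
candidate variable then gets its own model — variable plus adjustment terms,
the variable itself always linear, mirroring the screening design — and the
per-variable Wald p-values are BH-adjusted. Hazard ratios are also reported
on the log2 scale for forest plots.

## Interaction networks

Local exports only — no live database queries, for reproducibility; the two
supported dialects (two identifiers + integer combined score 0–1000;
miRNA/target/support) cover STRING and miRTarBase/TargetScan-style files, so
real exports drop in. Scores map to [0,1] (validated miRNA support 1.0,
predicted 0.5); duplicate undirected edges collapse to the maximum score;
identifiers match exactly, with an optional alias table instead of remote ID
conversion. Protein–protein edges survive iff both endpoints are in the DE
set; miRNA–gene edges iff both members are significant in their own analysis
with opposite-signed fold changes (an asserted invariant of the output
container). Edge strength is score × (|logFC_a| + |logFC_b|)/2 — a
multiplicative combination that is monotone in both inputs and balanced in
scale — with lexicographic tie-breaking for byte-identical output; the full
annotated table is always written alongside the top 100.

## Synthetic data

The generators are pure functions of a spec and seed and emit truth tables
sufficient to score every downstream recovery test. Continuous mode:
Gaussian noise (sd 1) around per-variable baselines N(7, 1.5), planted
log2-scale group shifts (default 5% of variables at ±2), additive batch
shifts, correlated blocks via a shared per-sample factor
(√r·f + √(1−r)·noise), MCAR masking. Count mode: negative-binomial via a
gamma–Poisson mixture with log-normal gene-wise dispersions (median 0.1,
log-sd 0.5), uniform 0.7–1.3 library-depth factors, multiplicative group
effects. Survival: exponential baseline scaled by exp(βx) with independent
exponential censoring whose rate is solved (bisection on the closed-form
expected censoring probability) to hit the requested fraction. The
`array80` preset mirrors the shape of an 80-sample two-group (61/19) array
study at 1500 variables — a desk-scale variable count chosen so the full
pipeline, tests, and acceptance script run in minutes; `ms-glycan` mirrors
a ~70-variable two-fluid mass-spectrometry study; `seq` is a balanced
30+30 count design.

What the generator does *not* emulate: variable-specific noise variances,
missingness that depends on abundance (MNAR, common in proteomics),
annotation structure, or any real biology. Passing recovery tests therefore
demonstrates correctness of the algorithms under their stated assumptions,
not performance on real cohorts.

## Numerical choices and limitations

- Coordinate-descent tolerance 1e-7 on the weighted quadratic decrease;
  IRLS capped at 10 passes per λ (warm starts make more unnecessary).
- Lowess span 0.5 and the 1e-4 sqrt-sd floor in the precision weights.
- Trigamma inversion by Newton from the 0.5 + 1/y start; non-positive
  excess variance of log s² yields d₀ = ∞ rather than a negative prior.
- Quantile-normalization ties take the mean of spanned reference values.
- k-means restarts 25; BIC ties resolved to the smallest k.
- MDS pads the second axis with zeros for exactly collinear samples instead
  of failing; only a fully degenerate (no positive eigenvalue) geometry is
  an error.
- The per-module hub fraction is arithmetic: ceil(top_frac · module size)
  with top_frac = 0.25 by default and exposed as an option.
- Not implemented by design: surrogate-variable estimation (batch handling
  is design-based), trended/robust variance priors, signed or hybrid
  topological overlap, dynamic tree cutting, Kaplan–Meier plotting,
  time-dependent covariates, competing risks, live database clients.
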