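# Methods

This note documents the statistical models, the numerical choices behind
them, what the synthetic-data generator does and does not emulate, and known
limitations. It is the design record for maintainers; the README covers usage.

## Standardized major axis (model II) regression

Species-mean traits are log10-transformed before any regression; base 10 is
load-bearing, since intercepts are reported on the log10 scale in the data's
raw units (g, cm). Both variables in an allometric pairing carry biological
and measurement error, so lines are fitted as the standardized major axis:

    b̂ = sign(r) · s_y / s_x,      â = ȳ − b̂·x̄.

**Slope CI.** The standard construction: with
`B = F(1−α; 1, n−2) · (1−r²)/(n−2)`, the limits are `b̂·(√(B+1) ∓ √B)`.
This interval is the exact inversion of the slope F-test below, so
CI-exclusion and test verdicts can never disagree (a property test enforces
it).

**Slope test.** A hypothesized slope `b0` is tested by rotating into residual
and axis scores `u = y − b0·x`, `v = y + b0·x`, which are uncorrelated under
the null; `F = r²_uv (n−2)/(1 − r²_uv)` on (1, n−2) df.

**Intercept CI.** The published tables print intercept intervals without a
formula. We use `Var(â) = s²_resid/n + x̄²·Var(b̂)` with `Var(b̂)` implied by
the slope CI half-width on the t scale. This is an approximation; on the
bundled data it matches the published intercept intervals to ~0.01, and it is
treated as accurate to ±0.05, not to printed precision.

**Common slope.** For each group, twice the gap between the free
bivariate-normal maximum likelihood and the profile likelihood at slope `b`
is `−n·log(1 − r²_uv(b))` (the Jacobian of the rotation cancels). The pooled
statistic is minimized over `b` by bounded scalar search (tolerance 1e−10)
within the range of the group slopes and referred to χ²(k−1). This is a
likelihood-ratio construction; other implementations use a score-type
statistic, so p-values match only approximately (simulated type-I error at
α = 0.05: 0.049).

**Elevation.** At the common slope, group elevations are `â_i = ū_i` with
`u = y − b̂_c·x`. Their covariance combines per-group residual variance
(`s²_u/n`) with the shared slope uncertainty, estimated as the inverse
observed information of the pooled profile likelihood (second difference,
step `1e−5·max(1, |b|)`), which enters as `Var(b̂_c)·x̄_i x̄_j`. The omnibus
Wald statistic uses k−1 difference contrasts with a pseudo-inverse so that
degenerate groups (duplicated, or zero residual variance) yield statistic 0
rather than a crash. The Wald form is mildly liberal at small n (simulated
type-I ≈ 0.068 at n = 30 per group). Pairwise post hoc tests are 1-df and
deliberately unadjusted: raw p-values are reported side by side with
effect-size CIs instead of applying a multiplicity correction that would
sacrifice power over ten non-independent pairings.

## Trait evolution on trees

Under Brownian motion with rate σ² along a rooted tree with branch lengths in
My, tip values are jointly normal with covariance σ²·C, `C_ij` the shared
root-to-MRCA path length. Two one-parameter deformations are fitted:

* **λ ∈ [0, 1]** multiplies off-diagonal entries: 0 = star phylogeny (no
  phylogenetic signal), 1 = BM. Values above 1 are not supported (the
  empirical intervals cap at 1).
* **δ ∈ (0, 3]** raises every entry (a node depth) to the power δ: δ > 1
  concentrates change toward the tips, δ < 1 toward the root, δ = 1 is BM.
  The transform is applied elementwise to C with **no total-depth rescaling**:
  rescaling variants change only the fitted σ̂², never likelihood orderings or
  δ̂, so the simpler convention is used and stated here. The upper bound 3 is
  the conventional search cap for this parameter. δ requires an ultrametric
  tree (equal tip depths), which is checked.

**Likelihood.** Root state and rate are profiled analytically:
`root = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹y`, `σ̂² = rᵀC⁻¹r/n` (ML, n denominator), giving
`logL = −(n/2)·ln(2π·σ̂²) − ½·ln|C| − n/2` via Cholesky. A Cholesky failure
triggers one jitter of `1e−10 ×` mean diagonal, then a hard numerical error.
A trait with numerically zero variance on the tree is rejected as degenerate
rather than silently fitted at the σ² = 0 boundary.

**Optimization.** A deterministic 13-point grid over the parameter range
locates the global basin; bounded scalar minimization refines within the
bracketing grid interval (parameter tolerance 1e−6, which keeps the
log-likelihood within its 1e−8 contract because the surface is locally
quadratic); exact boundary values are always evaluated as candidates. Ties
within 1e−8 log-likelihood break toward the value closest to 1 (the Brownian
reference), and boundary optima are flagged (`at_bound`). The fit agrees
with an independent R implementation (ape/phytools `phylosig`) to 4e−6 in λ
and 1e−9 in log-likelihood on a frozen 12-tip check.

**Bootstrap CIs.** Parametric: simulate n_sim datasets under the fitted
(θ̂, σ̂², root̂), refit, take the 2.5/97.5 percentiles. Default n_sim = 1000;
below 100 a warning is issued. On 38-tip, 110-My trees these intervals are
honest but wide — often spanning most of the parameter range — which is the
central caveat of the empirical analysis and is reproduced by the test suite.

## PGLS and co-diversification

PGLS solves the GLS normal equations through Cholesky whitening (tested to
1e−10 against whitened OLS and exactly against OLS at C = I). Coefficient CIs
use σ̂² with the n−2 denominator on t(n−2); the reported log-likelihood uses
the ML σ̂² (n denominator) so it is directly comparable to the
trait-evolution likelihoods. Residuals are species-indexed and feed the
co-diversification analysis, which by default uses the **Brownian** (i.e.
phylogenetic) covariance; the underlying functions also accept C = I for a
non-phylogenetic variant, since the original description of the residual
analysis does not pin this down.

## Monte-Carlo model comparison (λ vs δ)

The observed statistic is `logL(δ̂) − logL(λ̂)` (positive favors δ). For each
of the two fitted models, n_sim traits are simulated under its fitted
parameters, both models are refitted to every simulated trait with identical
optimizer settings, and the 2.5/97.5 percentiles of the simulated ratios form
that model's null band; a model is rejected when the observed ratio falls
outside its own band. Randomness derives from a single mandatory seed, with
each simulation arm on its own seed-sequence substream, so results are
bitwise reproducible and independent of evaluation order. Refit failures
above 1% of n_sim abort the run; below that they are replaced from a
dedicated retry substream so each null distribution holds exactly n_sim
values. Default n_sim = 1000; tests run at 100–200 with correspondingly loose
statistical tolerances.

Calibration measured by simulation at the study's scale (38 tips, 110 My,
generating λ = 0.8, n_sim = 200): the generating model is falsely rejected
2% of the time — conservative relative to the nominal 5%, as expected for a
parametric bootstrap with a bounded, re-estimated parameter. Discrimination
between λ and δ is intrinsically weak here: even traits generated at δ = 2.5
on 128-tip trees yield observed ratios of only a few log-units, so δ is
retained essentially always while λ is rejected in only ~a quarter of such
datasets. That near-indistinguishability at realistic sample sizes is a
finding, not a defect, and matches the empirical analysis's inability to
prefer either model.

## Segment proportions and CV equality

Shares divide each true segment mass (thigh, shank, tarsometatarsus, digits —
the pes is the sum of the last two and is excluded from the budget) by their
per-species total, so rows sum to 1. Equality of coefficients of variation
across segments is tested as homogeneity of log-scale dispersion: for
positive data with small-to-moderate CV, SD(log values) ≈ CV, so a
Levene-type test (absolute deviations from the group mean of logs, one-way
ANOVA) on log shares tests CV equality while inheriting the CV's scale
invariance. The original analysis cites a two-way ANOVA layout that is not
fully specified; this one-factor interpretation with species as the
observational unit holds its nominal size under equal-CV lognormal simulation
(measured 0.052 at α = 0.05, 1000 replicates). The published figure used an
unnamed 15-species subsample; the package computes over all species with
complete segment data instead.

## Synthetic data: what it emulates, what it does not

`simulate_yule_tree` draws pure-birth trees forward in time (waiting times
Exp(k·rate), uniform lineage choice, one extra stretch past the last split)
and can rescale depth exactly; the default emulation target is 38 tips and
110 My, the sample size and deepest divergence of the study.
`simulate_trait` draws from MVN(root·1, σ²·C_θ). `simulate_allometric_table`
draws log10 body mass **log-uniformly** over (1.26, 3.84) — matching the
empirical 18–6975 g span, and log-uniform rather than lognormal because the
study sampled deliberately across functional extremes — then builds each
segment as `10^(intercept + slope·log10 M + ε)` with iid or phylogenetically
correlated ε; default residual_sd = 0.19 reproduces the empirical R² ≈ 0.95.
Missing values are inserted completely at random (rate ≤ 0.3).

Not emulated: measurement error distinct from residual scatter, non-random
missingness (the real gaps are specimen-driven), clade structure in trait
values beyond what the tree covariance induces, per-segment differences in
slope or scatter, and non-ultrametric (fossil-bearing) trees. Passing tests
on synthetic tables therefore validate the statistical machinery, not claims
about data-collection artifacts.

One estimand subtlety: the generator places all residual scatter in y, so the
population standardized major axis is `slope·√(1 + sd²/(slope²·Var(log M)))`
— about 1.139 when the nominal slope is 1.11 at the default scatter. SMA
intervals cover that axis at the nominal rate; coverage of the nominal
conditional slope is necessarily lower (~0.85 measured). Tests assert
coverage of the axis.

## Reproduction fidelity and known limitations

* The bundled species means are stored exactly as published (two decimals for
  masses, one for body mass). Slopes re-derived from them match all published
  values at the printed 2-dp precision, as do the verdict patterns for
  isometry, common slope, and elevation — with one marginal exception: digit
  mass vs hindlimb length within Land Birds gives p = 0.047 here vs a
  published 0.060, flipping that single verdict at α = 0.05. Several R² and
  intercept cells differ in the third decimal. These gaps trace to the
  original analysis having used unrounded specimen data; two published
  intercepts additionally contradict their own published confidence intervals
  (the values re-derived here fall at the midpoints of those intervals).
* The analyses that require the study's time-calibrated phylogeny (trait
  models, PGLS, co-diversification tables) cannot be reproduced desk-side
  because that tree is not published; the pipeline supports a user-supplied
  Newick tree, and correctness is established instead by likelihood
  identities, dense-MVN and whitened-OLS oracles, an independent R
  cross-check, and parameter-recovery simulation.
* Elevation Wald tests are mildly liberal at small group sizes; pairwise
  p-values are unadjusted by design.
* Problem sizes in the test suite (n_sim 100–200, 10–100 outer replicates,
  trees of 16–128 tips) were chosen to make the statistical assertions stable
  at reasonable cost; defaults in the package itself follow the study
  (n_sim = 1000, α = 0.05, null slopes 1.0 and 3.0).
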