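# allomorph

Allometric scaling and evolutionary diversification of hindlimb segment
masses in neognath birds — and a general toolkit for the statistics involved.

## The problem

How a limb's mass is distributed along its length shapes the cost of moving
it: heavy distal segments are expensive to swing. Whether larger birds have
relatively lighter or heavier limb segments is a question about **allometry**
— how a segment's mass *m* scales with body size, `m = a · M^b`. Under
geometric similarity (isometry) segment mass scales as (body mass)^1.0 and as
(hindlimb length)^3.0; exponents above those nulls are positive allometry.
A companion question is **how** these traits diversified across the bird
phylogeny: did variation accumulate clock-like along the tree (Brownian
motion), is it decoupled from phylogeny, or concentrated toward the root or
the tips?

The package implements the complete analysis for a table of species means of
body mass (g), hindlimb length (cm), and the masses (g) of the five hindlimb
segments (thigh, shank, pes, tarsometatarsal segment, digits) across 38
neognath species, bundled as `allomorph.load_neognath()`. Every component
also works on synthetic data with known ground truth.

## What is inside

* **Model II regression (`allomorph.sma`)** — standardized major axis fits on
  log10 data: `b = sign(r)·SD(log y)/SD(log x)`, slope and intercept CIs,
  F-tests of hypothesized slopes, likelihood-ratio common-slope tests across
  groups, and Wald elevation tests with unadjusted post hoc pairs.
* **Trait-evolution models (`allomorph.phylo`)** — Brownian motion on a
  time-calibrated tree, with covariance `C_ij` = shared root-to-ancestor path
  length; Pagel's λ (off-diagonal multiplier, 0 = star phylogeny, 1 = BM) and
  δ (elementwise power of node depths, >1 = tip-concentrated change) fitted by
  profile maximum likelihood; parametric-bootstrap CIs.
* **PGLS (`allomorph.pgls`)** — generalized least squares regression under the
  phylogenetic covariance, `β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y`, with species-indexed
  residuals for co-diversification analyses.
* **Monte-Carlo model comparison (`allomorph.pmc`)** — parametric bootstrap of
  the λ-vs-δ likelihood ratio: simulate under each fitted model, build null
  ratio distributions, reject a model whose 95% band excludes the observed
  ratio.
* **Proportion variability (`allomorph.cv`)** — per-species segment shares of
  limb mass and equality tests for coefficients of variation via log-scale
  dispersion.
* **Synthetic data (`allomorph.simulate`)** — seeded Yule trees, traits drawn
  from transformed tree covariances, and allometric tables with configurable
  slope, scatter, and missingness.

## Worked example

```python
import allomorph as am

table = am.load_neognath()
pair = am.pair_complete(table, "body_mass", "thigh_mass")
fit = am.fit_sma(pair)
iso = am.test_slope(pair, b0=1.0)
```

With the bundled data this prints (see `examples/scaling_allometry.py`):

```
n = 38 species with both traits
slope      = 1.11  (95% CI 1.031, 1.194)
intercept  = -1.82 (log10 g)
R^2        = 0.9530
isometry F-test: p = 0.0065; CI excludes 1.0: True
```

The slope of 1.11 with a confidence interval excluding 1.0 says thigh mass
grows about 11% faster than proportionally with body mass: positive
allometry. Running the whole battery (`examples/segment_batteries.py`) shows
all five segments sharing that slope (common-slope p = 0.82) while differing
sharply in elevation (p < 1e-100) — proximal segments are heavier than distal
ones at every body size, but the *scaling* is uniform along the limb.

The remaining examples cover trait-evolution model fitting with bootstrap
intervals (`trait_evolution.py`), Monte-Carlo model comparison
(`model_comparison.py`), and the segment-share variability test
(`mass_proportions_cv.py`). A thin CLI wraps the same pipeline:

```bash
allomorph reproduce-tables --out results/
allomorph phylo --tree mytree.nwk --nsim 1000 --seed 1 --out results/
allomorph simulate --spec spec.txt --out results/
allomorph cv --out results/
```

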