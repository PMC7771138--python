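# Methods

`traitgrad` implements a trait-based community-assembly analysis for
plot-level vegetation surveys: weighted and unweighted community trait
statistics, an abundance-shuffling null model with rescaled effect sizes,
a decomposition of among-plot trait variation into interspecific and
intraspecific components, permutation tests of community-level trait
covariation, and a correlation-matrix PCA of the environmental gradient.
A synthetic community generator reproduces the statistical structure such
surveys have, so every stage can be exercised and calibrated end to end
without field data.

## Community statistics

For plot *j* with species relative covers *p<sub>ij</sub>* (summing to 1
over retained species) and plot-level species trait means
*x<sub>ij</sub>*:

- unweighted average: mean of *x<sub>ij</sub>* over the species present —
  a presence/absence view of the community;
- community-weighted mean: CWM<sub>j</sub> = Σ<sub>i</sub>
  *p<sub>ij</sub> x<sub>ij</sub>*;
- community-weighted variance: CWV<sub>j</sub> = Σ<sub>i</sub>
  *p<sub>ij</sub>* (*x<sub>ij</sub>* − CWM<sub>j</sub>)², the
  abundance-weighted *population* variance (it satisfies
  CWV = Σ *p x*² − CWM² identically, which the tests assert to 1e−9);
- unweighted dispersion: the *n*−1 sample variance of the
  *x<sub>ij</sub>*, used as the dependent variable of Levene's test.

The weighted and unweighted forms are deliberately asymmetric (population
vs sample variance): the weighted form is the standard CWV definition,
while the unweighted dispersion only ever enters rank- or
deviation-based procedures where the denominator convention cancels.

Species present in a plot but without trait measurements are dropped from
that plot's weights, which are renormalized over measured species; a plot
whose measured species represent less than `cover_threshold` (default
0.80) of cumulative raw cover is flagged incomplete and excluded from
weighted statistics rather than rejected. Weights are renormalized per
trait, so a species missing one trait still contributes to the others.

## Null model and effect sizes

The null model permutes a plot's relative-cover vector uniformly among
its own species. This conditions on the observed species list, richness
and abundance multiset (hence evenness) and destroys only the
cover–trait pairing. With `n_permutations` draws (default 9,999) the
observed CWV is located at quantile

q = (#{null < obs} + ½·#{null = obs}) / n_permutations,

and rescaled to an effect size ES = 2q − 1 ∈ [−1, 1]. Ties get half
weight so that a degenerate plot whose species all share one trait value
lands exactly at ES = 0; equality is judged at relative tolerance 1e−9,
and observed and null CWVs are computed with the same raw-moment formula
so exact ties are detected reliably. Plots with fewer than two retained
species carry a degenerate flag and no ES. Effect sizes are invariant
under affine transforms of the trait (CWV scales by *a*², ranks are
unchanged). Sub-seeds for each (plot, trait) stream deterministically
from the master seed via `numpy.random.SeedSequence` spawning, and each
output row records the sub-seed used.

Inference on ES vectors uses the two-tailed Wilcoxon signed-ranks test
(exact null distribution up to n = 25, normal approximation with
continuity correction beyond; zeros dropped). Spearman rank correlations
(average-rank ties, two-sided t-approximation) relate ES and trait
values to environmental variables. Levene's test (mean-centered by
default; median-centered Brown–Forsythe as an option) compares the
dispersion of unweighted trait values between elevation and aspect
classes; its default observational unit is the species-level plot means
pooled across plots, with plot-level averages as a config option. The
0/0 corners of the deviation ANOVA are resolved by convention: zero
between-group deviation signal gives F = 0, zero within-group spread
with a between-group difference gives F = ∞, and all-zero deviations are
flagged degenerate.

## Covariation permutation test

Correlating two community-weighted means across plots inflates Type I
error because both inherit the same abundance weights. The modified
permutation test therefore permutes the species-level values of one
trait among species — each species' plot-specific means and grand mean
travel together — rebuilds that trait's community averages under the
original weights, and recomputes Spearman's ρ; the two-sided p-value is
(1 + #{|ρ_null| ≥ |ρ_obs|}) / (n_permutations + 1). When a permutation
assigns a donor species that lacks a measurement in some plot, the
donor's grand mean substitutes. A config switch
(`covariation_permute="plot"`) instead permutes the per-plot averages
directly, the simpler construction some workflows use. Groups are the
four topographic positions (elevation × aspect, pooled across sites)
plus all plots; at least 4 plots are required per test.

## Variance decomposition

Following the specific-vs-fixed-average construction: per plot the
*total* average uses plot-specific species means, the *interspecific*
average substitutes species grand means under the same weights, and the
*intraspecific* average is their difference. Among-plot sums of squared
deviations from the respective grand means give SS_total, SS_inter and
SS_intra, with SS_cov the cross-product, so SS_total = SS_inter +
SS_intra + 2·SS_cov holds exactly (floating-point exactly, not just to
tolerance). Relative contributions are reported as signed fractions of
SS_total; the covariation share may be negative. The species grand mean
is the unweighted mean of the species' plot-level means over the plots
where it was measured — the fixed-average convention — so "no
intraspecific variation" (identical plot means everywhere) forces
SS_intra = 0 by construction. Paired t tests compare the per-trait
contribution shares between weightings; a zero-spread difference vector
is degenerate and reported with p = 1 by convention.

## Environmental gradient

PCA runs on the correlation matrix of the ten plot-level environmental
variables (average/max/min temperature, soil moisture, pH, NO₃-N, NH₄-N,
PO₄, total soil N, PAR) after centering and unit scaling. Eigenvalues
sum to 10; axes with eigenvalue > 1 are marked retained (Kaiser
criterion) but all are reported. Scores are the standardized data
projected on the eigenvectors. Signs are fixed by making the
largest-magnitude loading of each axis positive, so output is
deterministic. A constant variable is a hard error naming the variable.

## Synthetic data generator

The generator emulates the survey design: 2 sites × 4 topographic
positions (high/low elevation × north/south aspect) × 5 plots, a
100-species pool, percent cover per plot–species, 15 measured
individuals per species per plot for six traits (H cm, LA mm², SLA
mm²/mg, LDMC mg/g, LN mg/g, δ¹³C ‰), and ten environmental variables.

One latent **resource score** per plot drives everything. Position bases
are +1 (high-north, coolest/wettest/richest), +⅓, −⅓, −1 (low-south),
with within-position spread 0.3. The ten variables are noisy linear
readouts: per position, each variable has a (mean, sd) profile
calibrated to growing-season values typical of southern Appalachian
understory plots (e.g. soil moisture 15.1% high-north vs 12.7%
low-south; average temperature 18.3 vs 20.3 °C; total soil N 0.47 vs
0.14%), plus a correlation with the within-position resource residual
(moisture and soil N +0.6, temperatures −0.5, pH and PO₄ ≈ 0.1). The
PCA therefore recovers a dominant axis aligned with the latent score
(|r| ≈ 0.9 in the worked example) without the ten variables being
simple copies of it.

Species grand means are drawn from a multivariate normal on transformed
scales (natural log for the five positive traits, natural scale for
δ¹³C) whose correlation structure encodes the leaf economics spectrum
(SLA–LN +0.6, SLA–LDMC −0.6, LDMC–LN −0.4, H–LA +0.4, SLA–δ¹³C −0.3)
with log-scale SDs 0.25–0.8 (δ¹³C: 1.5 ‰). Each species' resource
optimum is correlated 0.7 with its standardized SLA (high-SLA species
favour resource-rich plots), with SD 0.8 on the resource-score scale.

Two filters act on the squared optimum–score mismatch *m²*:

- **presence**: occurrence probability logistic(α − γ_presence·*m²*),
  with α set from a baseline presence probability of 0.18 (≈ 18 species
  per 100-species pool per plot);
- **abundance**: conditional on presence, cover is lognormal with
  log-mean −γ_eff·*m²*/(1 + *m²*) and log-SD 1.0. The penalty is
  saturating: performance differences level off with niche distance,
  which keeps plots from collapsing onto a single dominant at high
  filter strength (an unbounded quadratic penalty makes the effect-size
  dial non-monotone because a near-monoculture's CWV quantile no longer
  reflects trait convergence). γ_eff = γ_abund·(1 +
  `stress_amplification`·stress), stress ∈ [0, 1] increasing toward the
  resource-poor end, so convergence is strongest where conditions are
  most limiting — the direction field studies report along temperature
  and moisture gradients.

Covers are normalized to percent, rounded to 0.1 (field resolution);
covers below 0.1% are recorded *at* 0.1% as trace occurrences rather
than dropped, because the species list is an observation the null model
conditions on. Traits are then "measured" for the most abundant species
up to `trait_cover_fraction` (default 0.85) of cumulative cover,
mimicking a protocol that samples species covering > 80%. Individual
trait values scatter around the species grand mean on the transformed
scale with SD `sigma_intra` (default: one third of the interspecific SD
per trait) and a directional component `plasticity`·`sigma_intra`·score
(default plasticity 0.5), so switching `sigma_intra` to 0 removes *all*
intraspecific structure at once and forces SS_intra = 0 exactly.
Defaults γ_presence = 0.5 and γ_abund = 1.5 encode filtering that is
stronger on abundance than on presence.

What the generator does *not* emulate: spatial autocorrelation between
plots, phylogenetic signal, dispersal limitation, subplot structure
(cover is generated at the plot level), measurement error in cover, and
trait–environment interactions beyond a single resource axis. Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated under these idealized conditions, not that any field dataset
satisfies them.

## Calibration and parameter-recovery experiments

Problem sizes were chosen so the whole suite runs on one CPU in a few
minutes:

- null calibration: replicate studies (40 plots each; 200 in the test
  suite, 300 in `scripts/acceptance.py`) with both filters off; effect
  sizes from 199 permutations of the focal trait (SLA); the Wilcoxon
  departure test should reject at 5% within two binomial standard
  errors. The ES construction is permutation-count invariant in
  distribution, so 199 draws test the same property as 9,999.
- parameter recovery: 50 paired replicates per filter strength
  γ_abund ∈ {0, 1, 4} with presence filtering off and full trait
  coverage; mean ES must fall with γ in nearly every pair (sign test).
  Full trait coverage is used here because the top-cover measurement
  rule truncates precisely the within-plot abundance–trait contrast the
  ES dial measures — with the default 0.85 fraction, the dial's signal
  is strongly damped, which is itself an informative property of such
  protocols.
- exhaustive checks: for plots with 2–5 species the Monte-Carlo
  quantile (9,999 shuffles) is compared with full S!-enumeration; the
  covariation test is compared against the exact 4!-permutation null on
  a 4-species, 6-plot fixture.

## Numerical conventions

- Relative covers must sum to 1 within 1e−9 per plot; weighted averages
  on trait-specific subsets renormalize explicitly.
- Undefined results (no species with trait data, fewer than 2 species
  for a variance, constant vectors for ρ) are NaN with a flag, never 0.
- Permutations are generated by `argsort` of uniform draws, vectorized
  per plot; covariation nulls are evaluated in chunks to bound memory.
- All randomness flows from a single master seed through
  `SeedSequence.spawn` in a fixed iteration order, so every output is
  byte-reproducible and every stochastic row records its sub-seed.

## Known limitations

- The log-transform option refuses δ¹³C (sign-ambiguous) rather than
  offering an offset transform.
- The covariation test's grand-mean fallback makes the null slightly
  conservative when many species lack plot-level measurements.
- Levene's species-level pooling treats species plot means as
  exchangeable observations within a factor level, ignoring the species
  identity crossing; the plot-level option avoids this at the cost of
  power.
- CSV round-trips preserve full float precision via repr formatting;
  editing outputs in spreadsheet software will not.
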