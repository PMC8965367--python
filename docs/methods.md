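# Methods

`pinkrrs` estimates the relative reproductive success (RRS) of
hatchery-origin Pink Salmon (*Oncorhynchus gorbuscha*) strays spawning in
natural streams, from pedigrees reconstructed out of incompletely sampled
carcass surveys. This note documents the models, the synthetic-data
generator, the numerical choices, and the limits of what the test suite
demonstrates.

## The estimation problem

Hatchery fish are identified by thermal otolith marks. Reproductive
success (RS) of a spawner is the number of sampled adult offspring
assigned to it by genetic parentage analysis two years later (Pink Salmon
have a fixed 2-year generation, so odd- and even-year lineages are
reproductively isolated). Unweighted RRS is

    RRS = mean RS of hatchery-origin parents / mean RS of natural-origin parents,

computed over *all* sampled candidate parents, including those assigned
zero offspring. Because neither parents nor offspring are exhaustively
sampled (no weirs; carcass surveys only), most assignments recover a
single parent (dyads) rather than a pair (triads), and absolute RS is
deflated by the offspring sampling fraction. Unbiased offspring thinning
deflates both origins equally, so RRS itself is unaffected in
expectation — but statistical power is, which is what the power module
quantifies.

## Parentage assignment

Genotypes come from a 298-amplicon panel (210 unlinked biallelic SNPs, 88
microhaplotypes treated as multi-allelic loci). Per locus, genotypes are
unordered allele pairs; no half-calls are accepted.

For each offspring the engine scores, per locus and summed over loci:

- `L_U(g_o)`: Hardy-Weinberg probability of the offspring genotype
  (hypothesis: no sampled parent);
- `L_PO(g_p, g_o)`: probability given one parent `g_p`, the other parent
  integrated over population allele frequencies;
- `L_trio(g_p1, g_p2, g_o)`: Mendelian probability given a parent pair.

Genotyping error uses a genotype-replacement model: each per-locus
likelihood is floored as `(1-ε)·L_model + ε·L_U`, with one ε for the whole
panel (default 0.0054, the background error rate of the assay this
package models; the error sensitivity convention is to double it). A
missing parent genotype at a locus contributes the marginal `L_U`; a
missing offspring genotype contributes nothing, so hypotheses with
different missingness remain on a common scale.

Hypotheses per offspring are: every sampled female as dam, every sampled
male as sire, the top-B females × top-B males as pairs (beam width B = 5;
exact at this panel's discrimination power since the true parents
dominate the single-parent rankings), and "no sampled parent". Priors
factorize by sex: a specific sampled female has prior `1/N_fmax` and the
unsampled-dam alternative carries `1 − n_f/N_fmax`, where `N_fmax` is the
escapement-based maximum number of female spawners (same for males); a
hypothesis's prior is the product of its two sex-side factors, so the
prior is a proper distribution. The best hypothesis is accepted iff its
normalized posterior reaches the threshold (default 0.90); ties at
machine precision are left unassigned.

This is deliberately *not* a full-probability Bayesian pedigree
reconstruction with sibship inference. At this panel's information
content (combined exclusion probabilities indistinguishable from 1,
posteriors ≈ 1) the simple prior-weighted engine reproduces the decision
surface of the heavier machinery; the package verifies this on synthetic
truth rather than assuming it.

Panel diagnostics: per-locus and combined exclusion probabilities for a
sole parent and for a second parent given a known first parent (computed
by exact enumeration over genotype states), and a Monte-Carlo
discrimination simulation of parent-offspring vs unrelated, full-sibling
and half-sibling pairs scored by the PO-vs-U log-likelihood ratio, with
error rates reported at the threshold giving empirical FPR ≤ 1e-4 on
unrelated pairs.

## RRS statistics

- **pHOS**: hatchery / (hatchery + natural) per stratum, unknown-origin
  fish excluded.
- **Profile-likelihood CI for RRS** (ratio of mean RS): the split of the
  `T_H + T_N` assigned offspring between origins is treated as binomial
  with `p(w) = w·n_H / (w·n_H + n_N)`; the MLE is
  `ŵ = (T_H/n_H)/(T_N/n_N)` and the 95% CI is the set of `w` with
  `2[lnL(ŵ) − lnL(w)] ≤ χ²₁(0.95) = 3.841`, solved by bracketed
  root-finding (closed-form inversion at the `T_H = 0` / `T_N = 0`
  boundaries: lower bound 0, upper bound ∞ respectively). Empirical
  coverage is verified by simulation (Poisson offspring totals), since
  the binomial-profile form is a modeling choice: the exact likelihood
  the cited CI construction used is not restated in the source study.
- **Permutation test** of RRS ≠ 1: two-sided label permutation of origin
  on the pooled RS vector, statistic = difference of means. Exhaustive
  enumeration (exact p) when the number of label arrangements is ≤ 1e5,
  else Monte-Carlo with the add-one correction,
  `p = (1 + #{|d*| ≥ |d_obs|}) / (1 + n_perm)`. Permutation p-values on
  discrete RS data are conservative (ties count against rejection), which
  the type-I-error simulations show is a small effect at study-like n.
- **Cross types**: matings reconstructed from triads only (a mating is
  observable only if it produced ≥ 1 sampled offspring), keyed female
  origin first (HH, HN, NH, NN), with pairwise permutation tests.
- **Covariate contrasts**: Welch two-sided t for body length; Wilcoxon
  rank-sum (exact for small samples, normal approximation with tie
  correction otherwise) for sample day and distance; per
  stream/year/sex stratum.

## Negative-binomial GLM

Per-parent RS is modeled as NB2 with a log link:
`E[RS] = exp(Xβ)`, `Var = μ + μ²/θ`. Fitting is by maximum likelihood
(statsmodels), with covariates standardized internally and coefficients
reported back in natural units. `AIC = −2·lnL + 2·(p + 2)` counts the
intercept and θ for every model uniformly. Deviance explained is
`1 − D_resid/D_null` with the null deviance evaluated at the fitted
model's θ.

The a-priori model set is every term subset over {length, length², day,
day², origin, location, sex} subject to: distance and intertidal never
co-occur (confounded — intertidal is distance dichotomized at the tidal
boundary); a squared term only accompanies its linear term; sex only in
combined-sex sets. That yields 54 models per sex (108 combined). Model
selection requires at least 30 assigned offspring per origin, flags
covariate pairs with |r| > 0.7, ranks by AIC (lexicographic tie-break),
and excludes non-convergent members with a warning.

Incident ratios are `exp(β)` per natural unit; the origin incident ratio
is the modeled RRS. For a *selected* model the CIs are
profile-likelihood intervals (each bound solves the χ²₁ likelihood-ratio
equation with nuisance parameters re-maximized via offset refits), the
convention for NB GLM coefficient reporting; Wald intervals are the
default during ranking, where only AIC matters.

Hierarchical partitioning fits all 2^v subsets of the variable blocks
(a squared term travels with its linear term as one block) and averages,
over hierarchy levels, the mean log-likelihood gain from adding each
block to every subset lacking it; percentages are normalized to 100. The
goodness-of-fit can be switched to deviance explained. Non-convergent
subsets are imputed from the nearest converged nested pair, with a
warning.

## Power simulation

Power to detect a true RRS under incomplete sampling: per replicate,
natural-origin RS for `n_N` parents ~ NB(mean m, size k) and
hatchery-origin RS for `n_H` parents ~ NB(m·RRS_true, k); each offspring
is retained independently with probability `p_sample` (per-offspring
binomial thinning); the two-sided permutation test is applied to the
thinned counts; power is the fraction of replicates with p ≤ α. Defaults:
α = 0.05, 2000 replicates, 1000 permutations inside each replicate.
"Dispersion 1 to 10" on the grid refers to the NB size parameter k
(variance m + m²/k), not to the variance itself.

Replicates are driven by per-replicate seed substreams with inverse-CDF
NB draws and shared per-offspring thinning uniforms, i.e. common random
numbers: cells simulated with the same seed are paired, so monotonicity
comparisons along the m, p_sample and parent-number axes are low-noise.
Grid cells share the seed by default (`share_seed=False` gives
independent per-cell streams). Counts above 512 per parent are truncated
in the thinning step; at the supported (m, k) ranges this event has
negligible probability. Heatmap-style interpolation is bilinear on the
(m, p_sample) plane per k level, clipped to [0, 1], with extrapolation
refused.

## Synthetic-data generator

The generator is first-class, tested code; it defines the conditions
every downstream claim is tested under.

- **Panel**: 210 SNPs with minor-allele frequencies uniform on
  [0.05, 0.5]; 88 microhaplotypes with 3–6 alleles and Dirichlet(1)
  frequencies floored at 0.01.
- **Spawners**: origin ~ Bernoulli(pHOS); sex ~ Bernoulli(0.5); length,
  sample day and distance upstream from origin/sex-specific normal laws.
  The defaults are the even-year (2014) Hogan Bay means and SDs — e.g.
  hatchery females 441.9 ± 19.4 mm vs natural 434.0 ± 20.4 mm, hatchery
  sample days ~2–5 days later, hatchery locations ~20–30 m further
  upstream — so origin is mildly confounded with every covariate, as in
  the field data. Truncation at biological bounds: length 250–600 mm,
  day-of-year 213–273, distance within the stream (default 550 m, the
  approximate Hogan Bay spawning-habitat length; intertidal boundary
  450 m, chosen so most of the habitat is tidally influenced).
- **Reproduction**: per female, offspring count ~ NB(μ_i, k) with
  log μ_i = log m + β·(covariates − centers); β_origin = log(RRS_true)
  applies to hatchery fish. Defaults: m = 3 surviving sampled-age adult
  offspring per natural female, k = 1, β_origin = log 0.5 (the effect
  size the study design targeted), β_length = 0.01/mm, β_day = −0.03/day,
  β_distance = −0.002/m — magnitudes matching the reported incident
  ratios; the day effect's sign varies between streams in the field data
  and one sign had to be fixed. Sires are drawn per offspring with
  probability ∝ the male's own μ times unit-mean gamma(k) noise, giving
  polygamous mating and overdispersed male RS; no mating model is
  specified by the source study, so this is a package design choice.
- **Genotypes**: founders from Hardy-Weinberg; offspring inherit one
  uniformly chosen allele per parent per locus, loci independent; then
  per individual-locus, genotype replaced by a fresh HWE draw with
  probability ε and set missing with probability `miss`.
- **Carcass sampling**: independent retention with probability
  `fraction · w(day)/max(w)`; without a bias function this is plain
  binomial thinning, origin-independent by construction.

What the generator does *not* emulate: multi-generation pedigrees and
grandparent effects, sibship structure informing assignment, spatially
explicit redds or density dependence, fishery harvest of offspring,
straying between streams, locus-specific error rates, and linkage between
amplicons. Passing tests therefore demonstrate correctness of the
estimators under the stated sampling model, not robustness to those
field realities; date-biased sampling can be injected through the bias
function but no claim of unbiasedness under it is made (it is exactly the
condition under which unweighted RRS is known to be vulnerable).

## Problem sizes in the checks

The shipped checks run at desk scale, chosen to exercise the same regime
as the study rather than its full size: 500 simulated offspring for exact
pedigree recovery (the study's own validation used 3000 per lineage);
2000 replicates for power-null calibration at the even-year Hogan-like
design point (n_H = 437, n_N = 214); 200-replicate reduced grids for
monotonicity; 1000 simulated datasets for CI coverage and permutation
type-I error; 20 full pipeline replicates (800 parents each) for
end-to-end recovery of RRS_true = 0.5. The 20-replicate recovery check
deserves a caveat: with a correctly calibrated 95% CI, requiring coverage
in ≥ 18 of 20 runs fails by Monte-Carlo chance roughly one time in ten;
its two rates are therefore also reported as continuous quantities by the
reproduction script.

## Numerical details

- All randomness flows from named, SHA-keyed seed substreams of one
  master seed; identical seeds give identical outputs across platforms.
- Mendelian exclusion with ε = 0 yields −∞ log-likelihoods, handled
  exactly (hypotheses drop out); with ε > 0 nothing is ever −∞.
- Allele-frequency estimates are floored at 1/(2N+1) and renormalized so
  no observed allele has probability 0.
- Degenerate inputs: all-missing offspring are unassigned; a stratum
  with no hatchery (or natural) parents yields an RRS row with an
  explanatory status instead of an exception; an all-zero RS response
  refuses the GLM; zero-variance contrast groups report p = 1 with a
  degeneracy flag.
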