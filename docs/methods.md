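# Methods

## Model

For each trait `t` (adjusted weights W120, W240, W365, W450, in kg) the
observation model is

    y_t = X_t b_t + Z_a a_t + Z_m m_t + Z_pe p_t + e_t

with fixed effects `b_t` (contemporary group = herd × birth-year × birth
quarter, calf sex, and a linear dam-age covariate on the traits where it
screens significant), direct breeding values `a_t` for every animal in the
pedigree, maternal breeding values `m_t` and permanent-environment effects
`p_t` attached to the dam. Maternal and permanent-environment effects are
fitted only for the pre-weaning traits (W120, W240), where the calf still
depends on milk and mothering; for W365/W450 the model collapses to a
direct-effects-only animal model. Stacking traits,

    (a, m) ~ N(0, G ⊗ A),   p ~ N(0, P ⊗ I),   e ~ N(0, R ⊗ I)

where `A` is the numerator relationship matrix from the pedigree, `G` is the
genetic covariance among the six effect dimensions (four direct + two
maternal), `P` the 2×2 permanent-environment covariance and `R` the 4×4
residual covariance. Derived parameters follow Willham's decomposition
(README formulas): per trait σ²_p = σ²_a + σ²_m + σ_am + σ²_pe + σ²_e with
absent terms zero.

## Data adjustment and filters

Raw records carry birth weight (BW), weaning weight (WW) at `weaning_age`
days, and a last adult weight (AW) at `last_age` days. Average pre-weaning
gain is (WW − BW)/weaning_age and post-weaning gain (AW − W240)/(last_age −
240); adjusted weights interpolate linearly (120/240 d from the pre-weaning
line, 240 + 125 and 240 + 210 d from the post-weaning line). Note the
post-weaning construction makes W450 an exact linear function of W240 and
W365 within a record — a property of the adjustment, not of biology — which
is one reason the genetic correlation between W365 and W450 is near unity.

Filter pipeline, in order, each stage logged with record/trait counts:
adjusted weights (structurally impossible rows excluded) → per-trait 3-SD
outlier rule, computed over the whole data set in a single pass (mean and SD
include the outliers; SD = 0 removes nothing) → contemporary-group coding →
groups with fewer than 3 non-missing records per trait blanked → progeny of
sires with fewer than 3 recorded offspring per trait blanked. The two
structural rules run once each, group rule first, without iteration, so a
group shrunk by the sire rule is not revisited. Records with unknown sire
are exempt from the sire rule (it addresses sires, and exempting them is the
conservative reading). A single lone outlier among n values can be at most
(n−1)/√n SDs from the mean, so the 3-SD rule only ever bites for n ≥ 11.

Fixed-effect screening fits the trait on sex, herd, year-season and dam age
jointly by least squares and reports partial F statistics,
F = (ΔSSE/Δdf)/MSE_full, with degrees of freedom from matrix ranks so
aliased columns are tolerated; perfect fits report F = 0 for an effect that
explains nothing on top of an exact model.

## Pedigree algebra

`relationship_matrix` is the quadratic-cost tabular method, kept as the
oracle for tests. Production code builds the sparse `A⁻¹` directly by
Henderson's rules: each animal contributes b·{(i,i): 1, (i,parent): −½,
(parent,parent): ¼, (sire,dam): ¼} with b the inverse Mendelian-sampling
variance — 2, 4/3, 1 for two/one/no known parents without inbreeding, or
1/(0.5 − 0.25(F_s + F_d)) etc. with inbreeding coefficients from the
Meuwissen–Luo algorithm (per-animal Cholesky-row accumulation, cost
proportional to pedigree depth). `with_inbreeding=True` is the default; the
uncorrected path exists for speed and for matching textbook examples.
Unknown parents are the token `0` (or an empty field); identifiers are
opaque strings mapped to indices in topological order.

## Gibbs sampler

Each iteration, in fixed order: (1) residual augmentation — records missing
a trait get that trait's residual drawn from the conditional normal given
the record's observed residuals under the current `R`, grouped by
missingness pattern for vectorisation; (2) a single-site Gauss–Seidel sweep
drawing every scalar location effect from its univariate normal full
conditional (the genetic prior enters through the sparse `A⁻¹` and `G⁻¹`;
fixed effects have a flat prior); (3) inverse-Wishart draws of `G` (scale =
`A⁻¹`-weighted cross-products of the stacked effect vectors, df = number of
pedigree animals + prior df), `P` (dam-effect cross-products) and `R`
(augmented residual cross-products over all records).

Priors. `flat` (default) is the improper constant-density limit of the
inverse-Wishart, df = −(dim+1), zero scale — full conditionals are proper
whenever the data counts exceed roughly twice the block dimension, which is
checked at setup. `weak` (df = dim + 2, scale 0.01·I) is a proper fallback
for very small fixtures where the improper prior can produce an improper
posterior.

Starting values: half the phenotypic variance of each trait to the residual,
the other half split equally among the genetic/permanent components present;
effects start at zero. Single-site (not blocked) location sampling is the
simplest scheme consistent with the classical implementations of this model
family; a blocked sampler is a natural extension point.

Reproducibility: one seeded `numpy.random.Generator` drives everything. The
compiled sweep kernel consumes a pre-drawn array of standard normals, so the
draw order (augmentation → sweep → G → P → R) pins the stream and runs are
bit-identical per package version. Chain presets: `desk`
(20,000/5,000/10 iterations/burn-in/thin) for interactive work and `paper`
(1,500,000/500,000/1,000) mirroring a production protocol.

Numerical notes. The sweep reports the first equation with non-positive
conditional precision (aliasing missed upstream) instead of continuing; scale
matrices are Cholesky-checked before each inverse-Wishart draw and failures
abort with the iterate number. Fixed-effect design matrices are built as full
contemporary-group dummies plus a sex contrast and centered covariate, then
rank-checked by pivoted QR with aliased columns dropped and logged.

The location sweep is validated three ways in the test suite: against the
closed-form scaled-inverse-χ² / GLS posterior in an intercept-only model,
against the mixed-model-equation solution with variance components held
fixed, and (during development) against exact two-dimensional numerical
integration of the marginal posterior of (σ²_a, σ²_e) on small pedigrees,
which the sampler reproduces to within Monte-Carlo error.

## Posterior summaries

`mean_of_ratios` (default) derives the genetic parameters at every retained
iterate and reports posterior mean, SD and 95% highest-density interval
(shortest interval, via arviz); `ratio_of_means` applies the formulas once
to the posterior-mean components — the only mode that can be checked
directly against a published table of posterior-mean components, which is
why both exist. The two agree when the posterior is tight and can differ at
the second decimal otherwise (ratios of means are not means of ratios).
Display rounding is two decimals, half away from zero.

## Diagnostics

Heidelberger–Welch: the standardized cumulative-sum bridge of the chain is
tested against its Brownian-bridge null via the Cramér–von Mises statistic,
with the spectral density at zero estimated from the mean of the lowest 10%
(at least 3) of the nonzero periodogram ordinates of the second half of the
chain; the limiting p-value uses the classical four-term Bessel-K series,
with statistics above 3 reported as p = 0 (the series degrades far in the
tail, where P(W > 3) < 1e-4). If the full chain is rejected at α = 0.05,
leading 10% blocks are dropped (up to 50%) and the test repeated. The
halfwidth test passes when 1.96·√(S₀/n) over the kept portion is below
ε = 0.1 of |mean|. Effective sample size uses n/(1 + 2Σρ) truncated by
Geyer's initial-positive-sequence rule on adjacent-lag pairs. A
zero-variance chain is reported as failed-with-reason, not an exception.
α and ε defaults follow common practice.

## Synthetic herd generator

Discrete generations: a founder cohort (default 750, sex ratio 1:1), then in
each of four offspring generations every previous-generation female produces
two calves by a sire drawn from a team of about one sire per five dams.
This yields ~3,000 recorded animals in a ~3,700-animal pedigree with
~300 sire families and ~1,500 dams. The sire:dam ratio is deliberately less
extreme than a real elite herd would use: with only tens of sire families
the realized genetic variance of a single simulated herd swings far from its
expectation, and no estimator — Bayesian or otherwise — can recover a truth
the realization does not carry. Hundreds of sire families keep the realized
parameters within a few percent of the generating values, which is what a
recovery test needs.

Breeding values follow the pedigree exactly: founders N(0, G), descendants
= parent average + Mendelian deviation with covariance G·(0.5 −
0.25(F_s + F_d)) (0.75 − 0.25F for one known parent). Phenotypes add
trait means (121.6/183.8/215.5/248.5 kg), per-level herd/year/season
effects drawn with SDs 8/6/5 kg, a male–female difference of 6/12/18/24 kg,
a dam-age slope of 1.5/1.0/0/0 kg/yr (nonzero only where the covariate
screens significant), dam permanent-environment effects, and a joint
N(0, R) residual. Missingness is completely at random per trait at rates
(0.08, 0, 0.36, 0.33), mirroring per-trait record counts of a
weaning-recorded herd. Default G, P and R are published posterior means for
pasture-raised Polled Nellore, with residual covariances set to zero because
none are published — a realistic stand-in for truth, not the study's data.

What the generator does **not** emulate: selection and assortative mating,
overlapping generations, genetic trend, heterogeneous variances across
herds, non-random missingness, and recording errors. Passing recovery tests
therefore show the estimator is consistent under the model's own
assumptions, not that real herd data satisfy them.

Raw-record mode inverts the adjustment formulas from (W120, W240, W365) with
random weaning and last-weighing ages; W450 is the implied value
W240 + 210·(W365 − W240)/125, exactly as in real data where both
post-weaning weights derive from the same pair of weighings.

## Problem sizes and tolerances in the tests

The recovery study uses the default design (~3,000 records) with chains of
30,000 iterations, 12,000 burn-in, thinning 12 — sized so that the slowly
mixing direct–maternal block has settled (verified by quarter-mean traces
and the Heidelberger–Welch test) while a full run stays in the minutes
range. At this scale the posterior SD of h²(W120) is ≈ 0.03–0.06 and the
across-realization spread of comparable size, hence the documented recovery
tolerances at the fixed test seed: ±0.10 for h²(W120) and for r_am(W120),
±0.07 for r_g(W365, W450). The direct–maternal correlation r_am is the
weakest-identified parameter of the model (posterior SD 0.06–0.2 at this
scale; separating σ_am from σ²_m and σ²_pe relies on sparse dam–offspring
contrasts), so the published-components worked examples, not desk-scale
recovery, are the check of the r_am arithmetic. The reproduction script
averages the recovered h² and r_g over three independent herd replicates
(same 30,000/12,000/12 chains, fresh herd and fresh chain stream each),
because a single realization's realized genetic parameters wander a few
percent from the generating truth — and a single chain carries comparable
Monte-Carlo error on the maternal axis — so the replicate mean is the
better estimate of what the method recovers under the stated conditions.

## Known limitations

- Single-site location sampling mixes slowly on the direct–maternal block;
  production-length chains (the `paper` preset) or a future blocked sampler
  are advisable for publication-grade intervals.
- The improper flat covariance prior is standard for this model family but
  yields improper posteriors on very small data sets; the setup check
  catches the diagnosable cases and the `weak` preset covers the rest.
- No genomic relationships, no unknown-parent groups, no heterogeneous
  residual variances, no REML mode.
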