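# Methods

This note documents the models, conventions and design choices behind
`meddiet`, in the spirit of a statistical-software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Intake arithmetic

Daily intake of an FFQ item is frequency (times/day) × portion size
(g). Item energy is energy density (kcal/100 g) × daily amount / 100;
participant energy is the sum over items. The phrase sometimes used for
FFQ energy derivation — "energy content times energy intake" — is
dimensionally circular; density × amount is the only consistent
reading and is what we implement. Food-group intakes are sums of item
intakes under a user-supplied item→group mapping (a synthetic catalog
is packaged for tests and simulation); fruits and nuts are combined
into a single component so the 9-component median-based score has
exactly nine entries. Intakes are used as raw g/day by default;
`ffq.energy_adjust` offers g/1000 kcal as an alternative because
adherence indices in the literature differ on this convention.

## Diet scores and boundary conventions

* Median components score favourably **at or above** the cutoff
  (ties count toward adherence), mirroring the original 0/1 index
  definition; the same closed-boundary rule is extended to tertiles,
  which are lower-closed intervals [0,t1), [t1,t2), [t2,∞).
* The ethanol window is closed, [5, 25] g/day. For the tertile-based
  index alcohol is scored dichotomously 0/2 (the index's source
  convention) rather than by tertile, since almost all pregnant
  participants report zero intake and tertiles would degenerate.
* A degenerate (constant) component yields t1 = t2; under the
  lower-closed rule all mass falls in the third tertile and a warning
  is emitted.
* Missing components exclude a participant from that score only, with
  a reason code; intakes are never imputed. A zero saturated-fat
  intake leaves the MUFA/SFA ratio undefined (reason-coded), so the
  9-component score is unavailable while the 7-component pregnancy
  score still computes.
* Cutoff tables are mandatory configuration with explicit provenance
  (`external_reference` vs `within_sample`); the packaged default is
  labelled illustrative and is aligned with the synthetic generator's
  intake distributions, not with any published reference population.
  Sex-specific cutoffs are supported via an optional key but an
  all-female pregnancy cohort uses a single table.
* Within-sample cutoffs use the sample median and the linearly
  interpolated 1/3 and 2/3 quantiles (numpy's default `linear` rule),
  chosen for determinism and continuity in n.

## Outcome

K6: six items 0–4, total 0–24, distress at total ≥ 13, report
categories ≤4 / 5–9 / 10–12 / ≥13. Any missing item makes the total
missing — no prorating — matching a selection design that excludes
incomplete outcome data.

## Selection cascade

Filters run in a fixed order (first participation → abortion/stillbirth
→ missing/improbable data → energy bounds → mental-illness history),
each step logged as (n_before, n_excluded, n_after) so order
sensitivity is auditable; a row matching several criteria is counted at
the first. Energy bounds are inclusive and accepted as configuration
(default 216.0–3253.9 kcal/day, a realized mean ± 2 SD window);
`energy_sd_bounds` recomputes mean ± 2·SD (ddof = 1) on new data.
"Improbable data" has no standard definition, so it is a pluggable
predicate defaulting to none. The cascade is idempotent.

## Imputation

Single kNN imputation for categorical covariates only (never outcome
or exposure): Hamming distance on categoricals, range-scaled absolute
difference on declared ordinals, averaged over the features observed
in the target row; the k = 5 nearest complete donors vote, modal value
wins. Determinism: equidistant donors are ordered by a seeded
permutation fixed per call, and modal ties break to the first-seen
category. k = 5 is a conventional default; the method deliberately
performs *single* imputation, so downstream variances carry no
imputation-uncertainty inflation — a documented limitation.

## Risk-ratio engine

Modified Poisson regression: Poisson GLM, log link, binary outcome.
IRLS solves (X'WX)β = X'Wz with W = μ and z = η + (y−μ)/μ, stopping
when the deviance changes by < 1e-8 (max 100 iterations; linear
predictors are clipped at ±30 during iteration to keep intermediate
means finite). The covariance is the HC0 sandwich — bread (X'WX)⁻¹,
meat Σ xᵢxᵢ'(yᵢ−μᵢ)² — with an HC1 flag; at the cohort sizes this
package targets (tens of thousands) the small-sample correction is
immaterial. CIs use z = 1.959964 exactly for bit-stable output.
Dummy coding uses declared reference levels, levels entering in order
of first appearance; rank-deficient designs are rejected with the
offending terms named. On a saturated single-binary-exposure design
the fit reduces analytically to the closed-form 2×2 risk ratio with
log-RR SE √((1−p₁)/a + (1−p₀)/c); the test suite checks this identity
to six significant digits and cross-checks general fits against an
independent GLM implementation.

Pearson's chi-square (no continuity correction) and VIF (1/(1−R²) per
design column, infinite under exact collinearity) round out the
diagnostics.

## Attributable fractions

Point estimate: PAF% = 100·Pe·(RR−1)/RR, the case-based (Miettinen)
form with Pe = proportion of cases exposed. The phrase "proportion of
cases within each category" is ambiguous between this and Levin's
population-exposure form; the case-based reading is the standard match
for the Pe(RR−1)/RR formula and is the default, with
`pe_is_population=True` giving Levin's form for sensitivity analysis.
Negative PAFs (protective exposures) are reported as-is, never
truncated at zero.

Delta-method CI: PAF is written as g(β, Pe) = 100·Pe·(1−exp(−β_e)).
By default the first-order variance propagates **both** the robust
coefficient covariance (analytic gradient 100·Pe·exp(−β_e), verified
against central finite differences at relative step 1e-6) **and** the
sampling variability of Pe, via influence functions: β̂ has influence
(X'WX)⁻¹xᵢ(yᵢ−μᵢ) and P̂e has influence yᵢ(eᵢ−Pe)/M (M = case count),
giving var(P̂e) = Pe(1−Pe)/M plus a β̂–P̂e covariance term. Treating Pe
as known (`pe_variance=False`) is offered for comparison but is
anticonservative away from the null: in our calibration simulations at
n = 20,000 its 95% intervals cover the true case-based AF about 92.5%
and 89.5% of the time at RR = 1.2 and 1.4 respectively, whereas the
joint propagation stays at 95.3–95.6% across RR ∈ {1.0, 1.2, 1.4}
(5,000 replicates; the acceptance suite re-checks a 1,200-replicate
version). The interval is formed on the PAF scale directly, untransformed.
A seeded percentile bootstrap over participants (B ≥ 200, degenerate
resamples redrawn and counted) serves as a model-free cross-check; in
joint multi-exposure models each exposure's PAF comes from the same
fit, and with a single exposure the joint path reduces exactly to the
single-exposure path.

## Synthetic cohort generator

What it emulates: per-component lognormal daily intakes (independent
on the log scale by default; an optional correlation matrix can be
supplied); categorical covariates drawn from packaged marginal
frequencies shaped like a large Japanese pregnancy cohort; ethanol
zero-inflated (3% drinkers, lognormal among them, median 8 g/day);
energy as scored-food energy topped up by an unscored "other foods"
item to a Normal(1950, 450) kcal/day total (truncated at 800), so the
±2 SD energy filter has realistic mass in its tails; selection flags
(repeat participation 6.4%, abortion/stillbirth 2%, mental-illness
history 3%).

Exposure is assigned by **scoring the simulated intakes** against the
cutoff table — not by a coin flip — so the scoring and regression
stages are exercised jointly. The packaged cutoffs sit 0.2024 log-SD
below each beneficial component's median (above, for meat), a constant
chosen analytically so that each of the seven binary components is
favourable with probability Φ(0.2024) ≈ 0.580 and hence
P(score ≥ 4) = 0.671 for independent components — a ~33%/67%
low/high split, the exposure structure the pipeline targets. Shifting
beneficial intake log-means down provably raises the low-adherence
share (a tested monotonicity property).

The outcome is Bernoulli with log-risk = log(baseline) +
log(RR_low)·1[low adherence] + covariate terms; baseline risk 0.023
and RR 1.41 give an overall distress prevalence near 2.6% at the
default adherence split. Any stratum whose risk would exceed 1 raises
an error naming it. K6 items are then drawn from a latent two-class
mixture — Binomial(4, 0.72) per item conditioned on total ≥ 13 for the
distressed class, Binomial(4, 0.22) conditioned on total ≤ 12
otherwise (rejection sampling) — with a configurable concordance
between the latent class and the realized cutoff side (default 1).

Confounding can be planted with `confounder_intake_effects`: covariate
levels shift beneficial-intake log-means (meat oppositely), making
diet depend on, e.g., education while education also carries a direct
outcome effect. Because the risk model is exactly log-linear in
exposure and covariates, the covariate-adjusted modified-Poisson
estimate is consistent for the planted conditional RR — the basis of
the end-to-end recovery checks.

What it does **not** emulate: real FFQ instruments or portion-size
heterogeneity, within-person correlation between food groups (beyond
the optional log-scale correlation), joint covariate dependence
(marginals only, unless confounding is planted), questionnaire-wave
timing, or informative missingness (injection is MCAR). Passing tests
therefore demonstrate the *estimators'* correctness and calibration
under the assumed data-generating structure, not robustness to the
messiness of real cohort data.

## Problem sizes in the checks

Calibration checks use n = 20,000 cohorts with 1,200 replicates per
risk ratio (Monte-Carlo SE ≈ 0.6% on a coverage proportion) and a
B = 500 bootstrap; end-to-end confounded recovery uses eight
replicates at n = 50,000; the headline-quantity script runs one
n = 80,000 generation plus six n = 50,000 replicates and finishes in
seconds. These sizes make coverage bands statistically meaningful
while keeping the default suite quick.

## Known limitations

* Single imputation understates covariate-missingness uncertainty.
* The delta CI is first-order; for very small case counts the
  bootstrap is preferable.
* Zero cells in 2×2 inputs are rejected rather than continuity-
  corrected.
* External-reference cutoff values from Mediterranean source
  populations are not bundled; the packaged table is illustrative and
  any substantive analysis must supply its own.
* The printed attributable fractions of published analyses are not
  always recoverable from published marginal counts alone (the PAF
  depends on the exact Pe definition and model used); this package
  reports the formula it documents and nothing else.
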