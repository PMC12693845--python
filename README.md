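# meddiet

Reusable analysis pipeline for nutrition epidemiology in pregnancy
cohorts: does low adherence to a Mediterranean-style diet raise the
risk of psychological distress, and what fraction of distress cases is
attributable to it?

The package takes food-frequency-questionnaire (FFQ) responses,
derives daily food-group intakes, computes three Mediterranean-diet
adherence indices, classifies psychological distress from the Kessler
6-item scale (K6), applies a participant-selection cascade, imputes
missing categorical covariates by k-nearest neighbours, estimates risk
ratios by modified Poisson regression with robust (sandwich) variance,
and reports population attributable fractions (PAF) with delta-method
confidence intervals. A seeded synthetic-cohort generator emulates the
data structure of a large pregnancy cohort so every stage is testable
without access to restricted data.

## The statistics at the core

**Diet scores.** Three indices are computed from daily intakes (g/day)
against a cutoff table:

* **MDS** (0–9): one point per component — beneficial components
  (vegetables, fruits+nuts, legumes, fish, cereals, MUFA/SFA ratio)
  score 1 at or above the median; detrimental components (dairy, meat)
  score 1 below it; ethanol 5–25 g/day scores 1. High adherence ≥ 5.
* **rMED** (0–18): 0/1/2 by intake tertile, with olive oil as the fat
  component and meat/dairy reverse-scored; ethanol in 5–25 g/day
  scores 2. High ≥ 11.
* **PMDS** (0–7): pregnancy variant — alcohol and the fat ratio are
  dropped, dairy counts as beneficial. High ≥ 4.

**Outcome.** K6 total (six items, each 0–4) with distress defined as
total ≥ 13.

**Risk ratios.** For binary outcome *Y* and exposure indicator *E*
(low adherence), a Poisson GLM with log link is fitted by IRLS,
log μᵢ = β₀ + β₁Eᵢ + γᵀzᵢ, and RR = exp(β₁). Standard errors use the
HC0 sandwich B⁻¹MB⁻¹ (B = X'WX the Fisher information of the working
model, M = Σᵢ xᵢxᵢ'(yᵢ−μᵢ)²), which is valid although the Poisson
variance is misspecified for Bernoulli data.

**Attributable fraction.** PAF% = 100 · Pe(RR − 1)/RR with Pe the
proportion of cases exposed (Miettinen's case-based form). Confidence
intervals propagate the joint first-order variability of β̂ and Pe via
influence functions (delta method); a percentile bootstrap is provided
as a cross-check.

## Worked example

Published 2×2 counts can drive the regression path directly. For a
contingency of 847 distress cases among 26,414 low-adherence women
versus 1,224 among 53,857 high-adherence women:

```python
>>> from meddiet import crude_rr_from_counts
>>> res = crude_rr_from_counts(847, 26414, 1224, 53857)
>>> res["rr_2dp"], res["ci_2dp"]
(1.41, (1.29, 1.54))
```

Low adherence carries a 1.41-fold risk of distress (95% CI 1.29–1.54);
the closed-form estimate and the sandwich-Poisson fit agree to better
than six significant digits. The same numbers are available from the
shell:

```bash
meddiet crude-rr 847 26414 1224 53857
```

A fully synthetic run of the whole pipeline:

```python
>>> from meddiet import RunConfig, SimulationConfig, run_pipeline
>>> cfg = RunConfig(synthetic=SimulationConfig(n_participants=20000, seed=1), seed=1)
>>> bundle = run_pipeline(cfg)
>>> bundle["rr_results"][["score", "model", "rr_2dp", "ci_lo_2dp", "ci_hi_2dp"]]
  score     model  rr_2dp  ci_lo_2dp  ci_hi_2dp
0   mds     crude    1.25       1.04       1.50
1   mds  adjusted    1.25       1.04       1.50
2  rmed     crude    1.19       0.91       1.56
3  rmed  adjusted    1.20       0.92       1.56
4  pmds     crude    1.48       1.24       1.78
5  pmds  adjusted    1.48       1.23       1.77
```

The generator plants a low-PMDS risk ratio of 1.41 by default; the
crude PMDS estimate above (1.48, CI 1.24–1.78) recovers it within
Monte-Carlo error at this cohort size. MDS and rMED carry no planted
effect of their own, but their low groups overlap the low-PMDS group
(the indices share most components), so they show attenuated
associations rather than exact nulls — the same dilution pattern the
joint two-score models in the bundle disentangle. The bundle also
contains the attrition log, baseline-characteristics and K6-by-group
tables, PAF estimates, and joint two-score models.

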