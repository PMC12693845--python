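"""Packaged defaults for the synthetic cohort and for tests.

Everything here is synthetic/illustrative: covariate marginal
frequencies shaped like a large Japanese pregnancy cohort, a small FFQ
item catalog with portion sizes and energy densities, per-component
lognormal intake parameters, and an illustrative external-reference
cutoff table aligned with those intake distributions.  Real analyses
must supply their own cutoff table and FFQ mapping.
"""

from __future__ import annotations

import numpy as np

from .scoring import CutoffTable

# ---------------------------------------------------------------------------
# Covariate marginal frequencies (counts; normalised at sampling time).
# Levels mirror the usual baseline-characteristics classification of a
# pregnancy cohort; missing categories are excluded (missingness is
# injected separately).
# ---------------------------------------------------------------------------
COVARIATE_MARGINALS: dict[str, dict[str, int]] = {
    "age_cat": {"<20": 905, "20-34": 59906, ">=35": 19446},
    "bmi_cat": {"underweight": 12919, "normal": 58972, "overweight": 8347},
    "parity": {"multiparity": 44851, "nulliparity": 33427},
    "multiple_pregnancy": {"singleton": 79480, "multiple": 791},
    "conception_method": {"spontaneous": 74307, "non_art": 3058, "art": 2549},
    "dm_gdm": {"no": 77544, "yes": 2350},
    "alcohol_status": {"never_or_quit": 71856, "continue": 8090},
    "smoking_maternal": {"not_smoking": 76257, "smoking": 3462},
    "smoking_paternal": {"not_smoking": 42148, "smoking": 36603},
    "marital_status": {"married": 76485, "unmarried": 2846, "divorced_widowed": 611},
    "employment": {"not_working": 28108, "working": 49637},
    "edu_maternal": {"junior_high": 3446, "high_school": 24799, "college": 51759},
    "edu_paternal": {"junior_high": 5504, "high_school": 28931, "college": 45096},
    "income": {"<200": 3984, "200-399": 25388, "400-599": 24913, ">=600": 20521},
    "region": {"hokkaido": 6531, "tohoku": 17631, "kanto": 9592, "chubu": 14644,
               "kinki": 13286, "chugoku": 2324, "shikoku": 5586, "kyusyu_okinawa": 10677},
    # pre-pregnancy diet-score group, used as an adjustment covariate
    "mds_mt1": {"low": 60803, "high": 19468},
}

# Reference level per covariate for dummy coding (first baseline category).
COVARIATE_REFERENCES: dict[str, str] = {
    "age_cat": "20-34", "bmi_cat": "normal", "parity": "multiparity",
    "multiple_pregnancy": "singleton", "conception_method": "spontaneous",
    "dm_gdm": "no", "alcohol_status": "never_or_quit",
    "smoking_maternal": "not_smoking", "smoking_paternal": "not_smoking",
    "marital_status": "married", "employment": "not_working",
    "edu_maternal": "college", "edu_paternal": "college",
    "income": ">=600", "region": "tohoku", "mds_mt1": "high",
}

# ---------------------------------------------------------------------------
# FFQ item catalog (synthetic): item -> (food group, portion g, kcal/100 g,
# weight of the item within its group's total intake).  "other_foods" is
# deliberately unmapped — it carries the energy of foods outside the
# scored groups.
# ---------------------------------------------------------------------------
ITEM_CATALOG: dict[str, dict] = {
    "leafy_greens":   {"group": "vegetables",  "portion_g": 60,  "energy_per_100g": 25,  "weight": 0.6},
    "root_vegetables": {"group": "vegetables", "portion_g": 80,  "energy_per_100g": 35,  "weight": 0.4},
    "fresh_fruit":    {"group": "fruits_nuts", "portion_g": 150, "energy_per_100g": 52,  "weight": 0.9},
    "nuts":           {"group": "fruits_nuts", "portion_g": 15,  "energy_per_100g": 600, "weight": 0.1},
    "tofu_beans":     {"group": "legumes",     "portion_g": 75,  "energy_per_100g": 90,  "weight": 1.0},
    "fish_seafood":   {"group": "fish",        "portion_g": 80,  "energy_per_100g": 130, "weight": 1.0},
    "rice":           {"group": "cereals",     "portion_g": 150, "energy_per_100g": 160, "weight": 0.7},
    "bread_noodles":  {"group": "cereals",     "portion_g": 100, "energy_per_100g": 250, "weight": 0.3},
    "meat_products":  {"group": "meat",        "portion_g": 70,  "energy_per_100g": 200, "weight": 1.0},
    "milk":           {"group": "dairy",       "portion_g": 200, "energy_per_100g": 65,  "weight": 0.7},
    "yogurt_cheese":  {"group": "dairy",       "portion_g": 90,  "energy_per_100g": 90,  "weight": 0.3},
    "olive_oil":      {"group": "olive_oil",   "portion_g": 5,   "energy_per_100g": 900, "weight": 1.0},
    "other_foods":    {"group": None,          "portion_g": 100, "energy_per_100g": 180, "weight": 1.0},
}


def default_item_mapping() -> dict[str, str]:
    """Item -> food-group mapping for the packaged catalog."""
    return {item: info["group"] for item, info in ITEM_CATALOG.items()
            if info["group"] is not None}


# ---------------------------------------------------------------------------
# Per-component lognormal intake parameters (mu, sigma on the log g/day
# scale).  Medians chosen as plausible daily intakes for a pregnant
# Japanese population (vegetables ~250 g, fish ~60 g, cereals ~400 g,
# olive oil rare); purely illustrative.
# ---------------------------------------------------------------------------
INTAKE_LOG_PARAMS: dict[str, tuple[float, float]] = {
    "vegetables":  (np.log(250.0), 0.50),
    "fruits_nuts": (np.log(150.0), 0.60),
    "legumes":     (np.log(60.0), 0.70),
    "fish":        (np.log(60.0), 0.60),
    "cereals":     (np.log(400.0), 0.35),
    "meat":        (np.log(80.0), 0.50),
    "dairy":       (np.log(150.0), 0.80),
    "olive_oil":   (np.log(2.0), 1.00),
    "mufa_g":      (np.log(18.0), 0.35),
    "sfa_g":       (np.log(16.0), 0.35),
}

# Offset (in SD units on the log scale) between the intake medians and
# the illustrative cutoffs.  With each binary component scoring
# favourably with probability Phi(z) this puts ~67% of simulated
# participants in the high-adherence group of the 7-component pregnancy
# score, i.e. about one third low — the exposure split the analysis
# pipeline is exercised against.
CUTOFF_OFFSET_Z = 0.2024139225291661
_TERTILE_Z = 0.43072729929545756  # Phi^{-1}(2/3)


def default_cutoffs() -> CutoffTable:
    """Illustrative external-reference cutoff table.

    Aligned with ``INTAKE_LOG_PARAMS`` so simulated cohorts have a
    realistic adherence split; NOT the Mediterranean reference values of
    any published source.
    """
    z = CUTOFF_OFFSET_Z
    medians: dict[str, float] = {}
    for comp in ("vegetables", "fruits_nuts", "legumes", "fish", "cereals", "dairy"):
        mu, sd = INTAKE_LOG_PARAMS[comp]
        medians[comp] = float(np.exp(mu - z * sd))
    mu, sd = INTAKE_LOG_PARAMS["meat"]
    medians["meat"] = float(np.exp(mu + z * sd))  # detrimental: below-cutoff favourable
    # fat ratio: lognormal with mu = mu_mufa - mu_sfa, sigma = sqrt(s1^2 + s2^2)
    mu_r = INTAKE_LOG_PARAMS["mufa_g"][0] - INTAKE_LOG_PARAMS["sfa_g"][0]
    sd_r = float(np.hypot(INTAKE_LOG_PARAMS["mufa_g"][1], INTAKE_LOG_PARAMS["sfa_g"][1]))
    medians["fat_ratio"] = float(np.exp(mu_r + 0.5244 * sd_r))

    tertiles: dict[str, tuple[float, float]] = {}
    for comp in ("vegetables", "fruits_nuts", "legumes", "fish", "cereals",
                 "olive_oil", "meat", "dairy"):
        mu, sd = INTAKE_LOG_PARAMS[comp]
        tertiles[comp] = (float(np.exp(mu - _TERTILE_Z * sd)),
                          float(np.exp(mu + _TERTILE_Z * sd)))
    return CutoffTable(medians=medians, tertiles=tertiles,
                       provenance="external_reference")
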