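"""Modified Poisson engine: closed-form identities, statsmodels
cross-check, chi-square and VIF diagnostics."""

import numpy as np
import pandas as pd
import pytest

from meddiet import (ModelSpec, crude_rr_2x2, expand_2x2, fit_modified_poisson,
                     pearson_chi2, vif)

TABLE2 = {
    "pmds": (847, 26414, 1224, 53857),
    "mds": (1603, 60803, 468, 19468),
    "rmed": (1918, 73786, 153, 6485),
}


def test_intercept_only_recovers_prevalence():
    df = pd.DataFrame({"y": [1] * 13 + [0] * 87})
    fit = fit_modified_poisson(df, ModelSpec(outcome="y"))
    assert np.exp(fit.coef("intercept")) == pytest.approx(0.13, rel=1e-10)


@pytest.mark.parametrize("score,expected", [
    ("pmds", (1.41, 1.29, 1.54)),
    ("mds", (1.10, 0.99, 1.21)),
    ("rmed", (1.10, 0.94, 1.30)),
])
def test_crude_rr_matches_published_contrasts(score, expected):
    rr, lo, hi = crude_rr_2x2(*TABLE2[score])
    assert (round(rr, 2), round(lo, 2), round(hi, 2)) == expected


def test_sandwich_poisson_equals_closed_form_to_six_digits():
    for counts in TABLE2.values():
        closed = crude_rr_2x2(*counts)
        df = expand_2x2(*counts)
        fit = fit_modified_poisson(df, ModelSpec(outcome="case", exposures=["exposed"]))
        poisson = fit.rr("exposed")
        for a, b in zip(closed, poisson):
            assert abs(a - b) / a < 1e-6


def test_matches_statsmodels_robust_glm():
    """Independent cross-check of coefficients and HC0 sandwich SEs."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(17)
    n = 4000
    x1 = rng.integers(0, 2, n)
    x2 = rng.choice(["a", "b", "c"], n)
    risk = 0.05 * np.exp(0.3 * x1 + 0.2 * (x2 == "b"))
    y = (rng.random(n) < risk).astype(int)
    df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})

    fit = fit_modified_poisson(df, ModelSpec(outcome="y", exposures=["x1"],
                                             covariates={"x2": "a"}))
    # rebuild the design in the fitted term order (dummy levels appear in
    # order of first occurrence)
    cols = {"intercept": np.ones(n), "x1": x1.astype(float),
            "x2[b]": (x2 == "b").astype(float), "x2[c]": (x2 == "c").astype(float)}
    X = np.column_stack([cols[t] for t in fit.terms])
    ref = sm.GLM(y, X, family=sm.families.Poisson()).fit(cov_type="HC0")
    assert fit.coefficients == pytest.approx(ref.params, rel=1e-6)
    assert np.sqrt(np.diag(fit.robust_covariance)) == pytest.approx(ref.bse, rel=1e-4)


def test_label_swap_symmetry():
    """Recoding exposure 0<->1 flips the log-RR sign and keeps its SE."""
    counts = TABLE2["pmds"]
    df = expand_2x2(*counts)
    fit = fit_modified_poisson(df, ModelSpec(outcome="case", exposures=["exposed"]))
    swapped = df.assign(exposed=1 - df["exposed"])
    fit2 = fit_modified_poisson(swapped, ModelSpec(outcome="case", exposures=["exposed"]))
    assert fit2.coef("exposed") == pytest.approx(-fit.coef("exposed"), rel=1e-8)
    assert fit2.robust_se("exposed") == pytest.approx(fit.robust_se("exposed"), rel=1e-8)


def test_covariance_symmetric_psd_and_ci_ordered():
    df = expand_2x2(*TABLE2["mds"])
    fit = fit_modified_poisson(df, ModelSpec(outcome="case", exposures=["exposed"]))
    cov = fit.robust_covariance
    assert np.allclose(cov, cov.T)
    assert (np.linalg.eigvalsh(cov) >= -1e-12).all()
    rr, lo, hi = fit.rr("exposed")
    assert 0 < lo <= rr <= hi


def test_rank_deficiency_rejected():
    df = pd.DataFrame({"y": [0, 1, 0, 1], "e1": [0, 1, 0, 1], "e2": [0, 1, 0, 1]})
    with pytest.raises(ValueError, match="rank deficient"):
        fit_modified_poisson(df, ModelSpec(outcome="y", exposures=["e1", "e2"]))


def test_non_binary_outcome_rejected():
    df = pd.DataFrame({"y": [0, 1, 2]})
    with pytest.raises(ValueError, match="binary"):
        fit_modified_poisson(df, ModelSpec(outcome="y"))


def test_zero_cell_2x2_rejected():
    with pytest.raises(ValueError, match="positive"):
        crude_rr_2x2(0, 100, 5, 100)


def test_equal_risks_give_unit_rr():
    rr, lo, hi = crude_rr_2x2(10, 100, 20, 200)
    assert rr == pytest.approx(1.0)
    assert lo < 1.0 < hi


# --- Pearson chi-square ----------------------------------------------------

def _distress_2x2(a, n1, c, n0):
    return np.array([[a, n1 - a], [c, n0 - c]])


def test_chi2_published_pvalues():
    _, df_, p_pmds = pearson_chi2(_distress_2x2(*TABLE2["pmds"]))
    assert df_ == 1 and p_pmds < 1e-4
    _, _, p_mds = pearson_chi2(_distress_2x2(*TABLE2["mds"]))
    assert round(p_mds, 2) == 0.08
    _, _, p_rmed = pearson_chi2(_distress_2x2(*TABLE2["rmed"]))
    assert round(p_rmed, 2) == 0.24


def test_chi2_matches_scipy():
    from scipy.stats import chi2_contingency
    tab = np.array([[30, 70, 45], [25, 80, 50]])
    stat, df_, p = pearson_chi2(tab)
    ref_stat, ref_p, ref_dof, _ = chi2_contingency(tab, correction=False)
    assert stat == pytest.approx(ref_stat)
    assert df_ == ref_dof
    assert p == pytest.approx(ref_p)


def test_chi2_expected_equals_observed_is_zero():
    tab = np.array([[10, 20], [20, 40]])  # rows proportional
    stat, _, p = pearson_chi2(tab)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi2_zero_marginal_rejected():
    with pytest.raises(ValueError, match="marginal"):
        pearson_chi2(np.array([[0, 0], [5, 5]]))


# --- VIF -------------------------------------------------------------------

def test_vif_independent_covariates_near_one(rng):
    n = 20_000
    df = pd.DataFrame({"y": rng.integers(0, 2, n),
                       "a": rng.integers(0, 2, n).astype(float),
                       "b": rng.integers(0, 2, n).astype(float)})
    v = vif(df, ModelSpec(outcome="y", exposures=["a", "b"]))
    assert v.max() < 1.05


def test_vif_duplicated_column_infinite(rng):
    n = 500
    a = rng.integers(0, 2, n).astype(float)
    df = pd.DataFrame({"y": rng.integers(0, 2, n), "a": a, "b": a})
    v = vif(df, ModelSpec(outcome="y", exposures=["a", "b"]))
    assert np.isinf(v["a"]) and np.isinf(v["b"])


def test_vif_correlated_pair_closed_form(rng):
    n = 200_000
    z = rng.standard_normal(n)
    a = 0.9487 * z + np.sqrt(1 - 0.9487**2) * rng.standard_normal(n)
    b = 0.9487 * z + np.sqrt(1 - 0.9487**2) * rng.standard_normal(n)
    # corr(a, b) ~ 0.9 -> VIF ~ 1/(1 - 0.81) = 5.26
    df = pd.DataFrame({"y": rng.integers(0, 2, n), "a": a, "b": b})
    v = vif(df, ModelSpec(outcome="y", exposures=["a", "b"]))
    assert v["a"] == pytest.approx(1 / (1 - 0.81), rel=0.05)
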