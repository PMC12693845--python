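"""Population attributable fractions from fitted risk-ratio models.

The point estimate follows the case-based (Miettinen) form

    PAF% = 100 * Pe * (RR - 1) / RR

where Pe is the proportion of *cases* that are exposed and RR the risk
ratio for the exposure.  Interval estimates propagate the robust
coefficient covariance through the delta method, or resample
participants (percentile bootstrap) as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression import Z95, ModelSpec, RRFit, fit_modified_poisson

__all__ = [
    "PAFResult",
    "paf_point",
    "paf_from_fit",
    "paf_delta_ci",
    "paf_bootstrap_ci",
    "paf_gradient_fd",
]


@dataclass
class PAFResult:
    exposure_name: str
    pe_cases_exposed: float
    rr_used: float
    paf_percent: float
    ci95: tuple[float, float]
    method: str
    n_cases: int = 0
    notes: str = ""

    def as_dict(self) -> dict:
        return {
            "exposure": self.exposure_name,
            "pe_cases_exposed": self.pe_cases_exposed,
            "rr": self.rr_used,
            "paf_percent": self.paf_percent,
            "ci_lo": self.ci95[0],
            "ci_hi": self.ci95[1],
            "method": self.method,
        }


def paf_point(pe: float, rr: float, *, pe_is_population: bool = False) -> float:
    """PAF in percent from an exposure proportion and a risk ratio.

    With ``pe_is_population=False`` (default) ``pe`` is the proportion of
    cases exposed and the case-based form 100*pe*(rr-1)/rr applies.
    With ``pe_is_population=True`` ``pe`` is the population exposure
    prevalence and Levin's form 100*pe*(rr-1)/(1 + pe*(rr-1)) is used
    instead (sensitivity-analysis alternative).
    """
    if not 0.0 <= pe <= 1.0:
        raise ValueError(f"pe must be in [0, 1], got {pe}")
    if rr <= 0:
        raise ValueError(f"rr must be positive, got {rr}")
    if pe_is_population:
        return float(100.0 * pe * (rr - 1.0) / (1.0 + pe * (rr - 1.0)))
    return float(100.0 * pe * (rr - 1.0) / rr)


def _pe_from_table(table: pd.DataFrame, outcome: str, exposure: str) -> tuple[float, int]:
    cases = table[table[outcome] == 1]
    n_cases = len(cases)
    if n_cases == 0:
        raise ValueError("no cases observed; Pe undefined")
    exposed_cases = int((cases[exposure] == 1).sum())
    if exposed_cases == 0:
        raise ValueError(f"no exposed cases for '{exposure}'; Pe undefined")
    return exposed_cases / n_cases, n_cases


def paf_from_fit(fit: RRFit, pe: float, exposure: str) -> float:
    """PAF% as the smooth function g(beta) = 100*pe*(1 - exp(-beta_e))."""
    return float(100.0 * pe * (1.0 - np.exp(-fit.coef(exposure))))


def paf_delta_ci(
    fit: RRFit,
    table: pd.DataFrame,
    exposure: str,
    *,
    outcome: str,
    pe_variance: bool = True,
) -> PAFResult:
    """Delta-method 95% CI for the PAF of one exposure term.

    Writes the PAF as g(beta, pe) = 100 * pe * (1 - exp(-beta_e)) with
    pe the observed proportion of cases exposed.  The first-order
    variance propagates the robust coefficient covariance through the
    analytic gradient (100*pe*exp(-beta_e) in the beta_e coordinate)
    and, by default, also the binomial sampling variability of pe and
    its influence-function covariance with beta-hat — both contribute
    at first order whenever the RR differs from 1, and dropping them
    gives anticonservative intervals.  ``pe_variance=False`` reverts to
    coefficient-only propagation (pe treated as known).  The interval
    is formed on the PAF scale directly.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; refusing to propagate its covariance")
    pe, n_cases = _pe_from_table(table, outcome, exposure)
    beta_e = fit.coef(exposure)
    point = float(100.0 * pe * (1.0 - np.exp(-beta_e)))

    grad_beta = np.zeros(len(fit.terms))
    grad_beta[fit.terms.index(exposure)] = 100.0 * pe * np.exp(-beta_e)
    var = float(grad_beta @ fit.robust_covariance @ grad_beta)

    if pe_variance:
        if fit.design is None:
            raise ValueError("fit carries no per-observation data; refit with "
                             "fit_modified_poisson to propagate pe variability")
        X, y, mu = fit.design, fit.y, fit.mu
        e = X[:, fit.terms.index(exposure)]
        m_cases = y.sum()
        # influence functions: beta-hat ~ bread @ X'(y - mu); pe-hat ~ y(e - pe)/M
        bread = np.linalg.inv(X.T @ (X * mu[:, None]))
        if_pe = y * (e - pe) / m_cases
        cov_beta_pe = bread @ (X.T @ ((y - mu) * if_pe))
        var_pe = float(np.sum(if_pe ** 2))       # = pe(1-pe)/M for binary y
        g_pe = 100.0 * (1.0 - np.exp(-beta_e))
        var += 2.0 * g_pe * float(grad_beta @ cov_beta_pe) + g_pe ** 2 * var_pe

    half = Z95 * np.sqrt(max(var, 0.0))
    return PAFResult(
        exposure_name=exposure,
        pe_cases_exposed=pe,
        rr_used=float(np.exp(beta_e)),
        paf_percent=point,
        ci95=(point - half, point + half),
        method="delta",
        n_cases=n_cases,
    )


def paf_gradient_fd(fit: RRFit, pe: float, exposure: str, *, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of g(beta); analytic cross-check."""
    grad = np.empty(len(fit.terms))
    j_e = fit.terms.index(exposure)
    for j in range(len(fit.terms)):
        h = rel_step * max(abs(fit.coefficients[j]), 1.0)
        for sign in (+1, -1):
            b = fit.coefficients.copy()
            b[j] += sign * h
            g = 100.0 * pe * (1.0 - np.exp(-b[j_e]))
            if sign > 0:
                g_plus = g
            else:
                g_minus = g
        grad[j] = (g_plus - g_minus) / (2 * h)
    return grad


def paf_bootstrap_ci(
    table: pd.DataFrame,
    spec: ModelSpec,
    exposure: str,
    *,
    B: int = 500,
    seed: int = 0,
) -> PAFResult:
    """Percentile bootstrap 95% CI for the PAF of one exposure term.

    Resamples participants with replacement, refits the model, and
    re-evaluates the PAF each time.  Resamples with zero exposed cases
    are redrawn (counted in ``notes``).
    """
    if B < 200:
        raise ValueError("B must be at least 200 for a stable percentile interval")
    rng = np.random.default_rng(seed)
    n = len(table)

    fit = fit_modified_poisson(table, spec)
    pe, n_cases = _pe_from_table(table, spec.outcome, exposure)
    point = paf_from_fit(fit, pe, exposure)

    draws = np.empty(B)
    redraws = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        boot = table.iloc[idx].reset_index(drop=True)
        try:
            pe_b, _ = _pe_from_table(boot, spec.outcome, exposure)
        except ValueError:
            redraws += 1
            if redraws > 50 * B:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        fit_b = fit_modified_poisson(boot, spec)
        draws[b] = paf_from_fit(fit_b, pe_b, exposure)
        b += 1

    lo, hi = np.percentile(draws, [2.5, 97.5])
    return PAFResult(
        exposure_name=exposure,
        pe_cases_exposed=pe,
        rr_used=float(np.exp(fit.coef(exposure))),
        paf_percent=point,
        ci95=(float(lo), float(hi)),
        method="bootstrap",
        n_cases=n_cases,
        notes=f"B={B}, redrawn={redraws}",
    )
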