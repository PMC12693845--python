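"""Risk-ratio estimation for binary outcomes.

Modified Poisson regression — a Poisson GLM with log link applied to a
0/1 outcome — yields risk ratios directly as exponentiated coefficients.
Because the Poisson variance is misspecified for Bernoulli data, standard
errors come from the robust (sandwich) estimator, which is consistent
under the working-model misspecification.

Also provides the closed-form 2x2 crude risk ratio (an analytic special
case of the sandwich-Poisson fit on a saturated binary-exposure design),
Pearson's chi-square test, and variance-inflation-factor diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# Fixed normal quantile for 95% intervals, kept at this precision so CI
# output is bit-stable across platforms.
Z95 = 1.959964

__all__ = [
    "ModelSpec",
    "RRFit",
    "fit_modified_poisson",
    "crude_rr_2x2",
    "pearson_chi2",
    "vif",
    "expand_2x2",
    "build_design",
]


@dataclass
class ModelSpec:
    """Description of one risk-ratio model.

    Parameters
    ----------
    outcome:
        Name of the binary (0/1) outcome column.
    exposures:
        Indicator (0/1) columns entered as-is; one or several scores may
        be entered jointly.
    covariates:
        Mapping from categorical covariate column to its reference level.
        Each covariate is dummy-coded against its reference.
    """

    outcome: str
    exposures: list[str] = field(default_factory=list)
    covariates: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.exposures) & set(self.covariates)
        if overlap:
            raise ValueError(f"columns listed as both exposure and covariate: {sorted(overlap)}")


@dataclass
class RRFit:
    """A fitted log-linear risk model with robust covariance.

    Carries the design matrix, outcome and fitted means so downstream
    influence-function computations (e.g. attributable-fraction CIs)
    need no refitting.
    """

    terms: list[str]
    coefficients: np.ndarray          # log-RR scale, intercept first
    robust_covariance: np.ndarray
    n_used: int
    converged: bool
    iterations: int
    deviance: float
    design: np.ndarray | None = field(default=None, repr=False)
    y: np.ndarray | None = field(default=None, repr=False)
    mu: np.ndarray | None = field(default=None, repr=False)

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def robust_se(self, term: str) -> float:
        i = self.terms.index(term)
        return float(np.sqrt(self.robust_covariance[i, i]))

    def rr(self, term: str) -> tuple[float, float, float]:
        """Risk ratio and 95% CI for one term: (point, lo, hi)."""
        b, se = self.coef(term), self.robust_se(term)
        return (float(np.exp(b)), float(np.exp(b - Z95 * se)), float(np.exp(b + Z95 * se)))

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            point, lo, hi = self.rr(t)
            rows.append({"term": t, "log_rr": self.coef(t), "robust_se": self.robust_se(t),
                         "rr": point, "ci_lo": lo, "ci_hi": hi})
        return pd.DataFrame(rows)


def build_design(table: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Build (X, y, term names) with intercept and dummy-coded covariates.

    Exposure columns must already be 0/1 indicators.  Categorical
    covariates are expanded to one indicator per non-reference level.
    """
    y = np.asarray(table[spec.outcome], dtype=float)
    bad = ~np.isin(y, (0.0, 1.0))
    if bad.any():
        raise ValueError(f"outcome '{spec.outcome}' must be binary 0/1; "
                         f"found {np.unique(y[bad])[:5]}")

    cols = [np.ones(len(table))]
    names = ["intercept"]
    for e in spec.exposures:
        x = np.asarray(table[e], dtype=float)
        if not np.isin(x, (0.0, 1.0)).all():
            raise ValueError(f"exposure '{e}' must be a 0/1 indicator")
        cols.append(x)
        names.append(e)
    for cov, ref in spec.covariates.items():
        levels = pd.unique(table[cov].dropna())
        if ref not in set(levels):
            raise ValueError(f"reference level {ref!r} not observed in covariate '{cov}'")
        for lev in levels:
            if lev == ref:
                continue
            cols.append((table[cov] == lev).to_numpy(dtype=float))
            names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns); "
            f"check for aliased terms among {names}")
    return X, y, names


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    # y log(y/mu) with the 0 log 0 -> 0 convention
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(ylogy - (y - mu)))


def fit_modified_poisson(
    table: pd.DataFrame,
    spec: ModelSpec,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
    hc1: bool = False,
) -> RRFit:
    """Fit a Poisson GLM with log link by IRLS and attach sandwich SEs.

    The iteratively reweighted least squares update solves the weighted
    normal equations (X' W X) beta = X' W z with W = mu and working
    response z = eta + (y - mu)/mu, iterating until the change in
    deviance falls below ``tol`` (or ``max_iter`` is hit).

    The covariance is the HC0 sandwich: bread = (X' W X)^-1 (the inverse
    Fisher information of the working Poisson model), meat = sum of
    per-observation score outer products X' diag((y - mu)^2) X.  With
    ``hc1=True`` the meat is scaled by n/(n - p).
    """
    X, y, names = build_design(table, spec)
    n, p = X.shape

    # start from the intercept-only solution; guard log(0)
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1.0 / n))
    eta = X @ beta
    mu = np.exp(eta)
    dev = _poisson_deviance(y, mu)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = eta + (y - mu) / mu
        WX = X * mu[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        eta = X @ beta_new
        # cap eta to keep mu finite during intermediate steps
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        dev_new = _poisson_deviance(y, mu)
        beta = beta_new
        if abs(dev_new - dev) < tol:
            dev = dev_new
            converged = True
            break
        dev = dev_new
    if not converged:
        raise RuntimeError(f"IRLS did not converge in {max_iter} iterations "
                           f"(last deviance change at iteration {it})")

    WX = X * mu[:, None]
    bread = np.linalg.inv(X.T @ WX)
    resid = y - mu
    meat = (X * (resid ** 2)[:, None]).T @ X
    if hc1:
        meat = meat * (n / (n - p))
    cov = bread @ meat @ bread
    cov = (cov + cov.T) / 2.0  # enforce symmetry against round-off

    return RRFit(terms=names, coefficients=beta, robust_covariance=cov,
                 n_used=n, converged=converged, iterations=it, deviance=dev,
                 design=X, y=y, mu=mu)


def crude_rr_2x2(
    cases_exposed: int,
    n_exposed: int,
    cases_unexposed: int,
    n_unexposed: int,
) -> tuple[float, float, float]:
    """Closed-form crude risk ratio with 95% CI from a 2x2 table.

    RR = (a/n1)/(c/n0); the log-RR standard error is
    sqrt((1 - p1)/a + (1 - p0)/c), which coincides with the HC0
    sandwich SE of the saturated binary-exposure Poisson model.

    Returns ``(rr, ci_lo, ci_hi)``.
    """
    a, n1, c, n0 = cases_exposed, n_exposed, cases_unexposed, n_unexposed
    if min(a, c) <= 0 or min(n1, n0) <= 0:
        raise ValueError("all cells must be positive; continuity corrections for "
                         "zero cells are out of scope")
    if a > n1 or c > n0:
        raise ValueError("cases cannot exceed group size")
    p1, p0 = a / n1, c / n0
    rr = p1 / p0
    se = np.sqrt((1 - p1) / a + (1 - p0) / c)
    return (float(rr), float(rr * np.exp(-Z95 * se)), float(rr * np.exp(Z95 * se)))


def expand_2x2(
    cases_exposed: int,
    n_exposed: int,
    cases_unexposed: int,
    n_unexposed: int,
    *,
    exposure: str = "exposed",
    outcome: str = "case",
) -> pd.DataFrame:
    """Expand aggregate 2x2 counts into one row per individual.

    Lets printed contingency tables drive the regression path directly.
    """
    if cases_exposed > n_exposed or cases_unexposed > n_unexposed:
        raise ValueError("cases cannot exceed group size")
    e = np.repeat([1, 1, 0, 0], [cases_exposed, n_exposed - cases_exposed,
                                 cases_unexposed, n_unexposed - cases_unexposed])
    y = np.repeat([1, 0, 1, 0], [cases_exposed, n_exposed - cases_exposed,
                                 cases_unexposed, n_unexposed - cases_unexposed])
    return pd.DataFrame({exposure: e, outcome: y})


def pearson_chi2(table: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c table.

    No continuity correction.  Returns ``(statistic, df, p)``.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal total")
    expected = row @ col / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def vif(table: pd.DataFrame, spec: ModelSpec) -> pd.Series:
    """Variance inflation factors for the non-intercept design columns.

    VIF_j = 1/(1 - R^2_j) where R^2_j comes from regressing column j on
    the remaining columns (with intercept).  Perfect collinearity is
    reported as ``inf`` for the offending terms.
    """
    X, _, names = _design_allow_collinear(table, spec)
    if X.shape[1] < 3:  # intercept + at least two terms
        raise ValueError("need at least two model terms for VIF")
    out = {}
    for j in range(1, X.shape[1]):
        xj = X[:, j]
        others = np.delete(X, j, axis=1)
        coef, _, _, _ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ coef
        sst = float(((xj - xj.mean()) ** 2).sum())
        ssr = float((resid ** 2).sum())
        if sst == 0:
            out[names[j]] = np.inf
            continue
        r2 = 1.0 - ssr / sst
        out[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def _design_allow_collinear(table: pd.DataFrame, spec: ModelSpec):
    """Design matrix without the full-rank check (VIF must see aliasing)."""
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for e in spec.exposures:
        cols.append(np.asarray(table[e], dtype=float))
        names.append(e)
    for cov, ref in spec.covariates.items():
        for lev in pd.unique(table[cov].dropna()):
            if lev == ref:
                continue
            cols.append((table[cov] == lev).to_numpy(dtype=float))
            names.append(f"{cov}[{lev}]")
    y = np.asarray(table[spec.outcome], dtype=float) if spec.outcome in table else None
    return np.column_stack(cols), y, names
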