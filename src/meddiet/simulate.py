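"""Seeded synthetic pregnancy cohorts for pipeline testing.

The generator emulates the statistical structure the analysis assumes:

* per-component daily food intakes drawn lognormal (independent by
  default, optional correlation on the log scale);
* categorical covariates sampled from packaged marginal frequencies;
* diet-score exposure assigned by *actually scoring* the simulated
  intakes against a cutoff table, so scoring and regression are
  integration-tested together;
* a binary distress outcome generated from a log-linear risk model
  (baseline risk x exposure RR x covariate RRs);
* six K6 item responses generated from a latent two-class mixture so
  the instrument-level scorer sees realistic data;
* optional confounding via covariate-driven shifts of the intake
  log-means, and MCAR missingness injection.

Identical seeds give field-for-field identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import defaults
from .ffq import FOOD_GROUPS
from .scoring import CutoffTable, score_pmds

__all__ = ["SimulationConfig", "generate_cohort", "inject_missingness",
           "ffq_long", "save_cohort", "simulate_binary_cohort"]

K6_COLUMNS = [f"k6_item{i}" for i in range(1, 7)]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort draw.

    The defaults reproduce the study conditions the pipeline is built
    for: ~2.6% overall distress prevalence (baseline risk 2.3% in the
    high-adherence reference group times a low-adherence RR of 1.41 at
    a ~33% low share), covariate marginals shaped like a large Japanese
    pregnancy cohort, and intakes whose adherence split matches the
    packaged cutoff table.
    """

    n_participants: int = 1000
    seed: int = 0
    baseline_risk: float = 0.023
    true_rr_low_pmds: float = 1.41
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)  # level -> log-RR
    confounder_intake_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    intake_log_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(defaults.INTAKE_LOG_PARAMS))
    intake_log_correlation: np.ndarray | None = None  # over FOOD_GROUPS order
    energy_mean_sd: tuple[float, float] = (1950.0, 450.0)
    drinker_rate: float = 0.03
    ethanol_log_params: tuple[float, float] = (np.log(8.0), 1.0)
    k6_concordance: float = 1.0  # P(total >= 13 | latent distress)
    missingness_rates: dict[str, float] = field(default_factory=dict)
    flag_rates: dict[str, float] = field(default_factory=lambda: {
        "repeat_participation": 0.064, "abortion_stillbirth": 0.02,
        "mental_illness_history": 0.03})
    cutoffs: CutoffTable | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name, p in [("baseline_risk", self.baseline_risk),
                        ("drinker_rate", self.drinker_rate),
                        ("k6_concordance", self.k6_concordance),
                        *self.flag_rates.items(),
                        *self.missingness_rates.items()]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name}={p} outside [0, 1]")
        if self.true_rr_low_pmds < 0:
            raise ValueError("true_rr_low_pmds must be >= 0")


def _sample_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    out = {}
    for cov, counts in defaults.COVARIATE_MARGINALS.items():
        levels = list(counts)
        probs = np.array(list(counts.values()), dtype=float)
        probs /= probs.sum()
        out[cov] = rng.choice(levels, size=n, p=probs)
    return pd.DataFrame(out)


def _sample_intakes(rng: np.random.Generator, n: int, cfg: SimulationConfig,
                    covariates: pd.DataFrame) -> pd.DataFrame:
    comps = list(cfg.intake_log_params)
    mus = np.array([cfg.intake_log_params[c][0] for c in comps])
    sds = np.array([cfg.intake_log_params[c][1] for c in comps])

    # per-participant log-mean shifts from confounding covariates
    shift = np.zeros((n, len(comps)))
    for cov, by_level in cfg.confounder_intake_effects.items():
        lv = covariates[cov].to_numpy()
        for level, delta in by_level.items():
            mask = lv == level
            # shift beneficial food groups; meat moves the opposite way
            for j, c in enumerate(comps):
                if c in ("vegetables", "fruits_nuts", "legumes", "fish",
                         "cereals", "dairy"):
                    shift[mask, j] += delta
                elif c == "meat":
                    shift[mask, j] -= delta

    if cfg.intake_log_correlation is not None:
        corr = np.asarray(cfg.intake_log_correlation, dtype=float)
        if corr.shape != (len(comps), len(comps)):
            raise ValueError("correlation matrix shape must match the component list")
        z = rng.multivariate_normal(np.zeros(len(comps)), corr, size=n,
                                    method="cholesky")
    else:
        z = rng.standard_normal((n, len(comps)))
    log_intake = mus + shift + z * sds
    return pd.DataFrame(np.exp(log_intake), columns=comps)


def _k6_items(rng: np.random.Generator, realized_distress: np.ndarray) -> np.ndarray:
    """Item vectors by rejection from per-class ordinal distributions.

    Distressed side: items ~ Binomial(4, 0.72) conditioned on total>=13;
    non-distressed: Binomial(4, 0.22) conditioned on total<=12.
    """
    n = len(realized_distress)
    items = np.zeros((n, 6), dtype=int)
    unresolved = np.ones(n, dtype=bool)
    p = np.where(realized_distress, 0.72, 0.22)
    for _ in range(200):
        idx = np.flatnonzero(unresolved)
        if len(idx) == 0:
            break
        draw = rng.binomial(4, p[idx][:, None], size=(len(idx), 6))
        total = draw.sum(axis=1)
        ok = np.where(realized_distress[idx], total >= 13, total <= 12)
        items[idx[ok]] = draw[ok]
        unresolved[idx[ok]] = False
    if unresolved.any():
        raise RuntimeError("K6 rejection sampling failed to resolve all rows")
    return items


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate one synthetic raw cohort table.

    One row per participant with FFQ item frequencies (``ffq_freq_*``),
    per-component intakes (g/day), nutrient fields (MUFA/SFA/ethanol),
    energy, covariates, selection flags, K6 items, and oracle-only
    ``true_*`` columns (the latent exposure indicator and risk).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    cutoffs = cfg.cutoffs or defaults.default_cutoffs()

    covariates = _sample_covariates(rng, n)
    intakes = _sample_intakes(rng, n, cfg, covariates)

    # ethanol: mostly zero, lognormal among the few drinkers
    is_drinker = rng.random(n) < cfg.drinker_rate
    eth = np.zeros(n)
    eth[is_drinker] = np.exp(rng.normal(*cfg.ethanol_log_params, size=int(is_drinker.sum())))
    intakes["ethanol_g"] = eth

    # energy: scored-food energy plus an unscored "other foods" item that
    # tops intake up to a normally distributed total
    scored_energy = np.zeros(n)
    for item, info in defaults.ITEM_CATALOG.items():
        if info["group"] is None:
            continue
        scored_energy += (intakes[info["group"]] * info["weight"]
                          * info["energy_per_100g"] / 100.0).to_numpy()
    e_mean, e_sd = cfg.energy_mean_sd
    target = np.clip(rng.normal(e_mean, e_sd, size=n), 800.0, None)
    other_energy = np.maximum(target - scored_energy, 50.0)
    other_info = defaults.ITEM_CATALOG["other_foods"]
    intakes["other_foods"] = other_energy / (other_info["energy_per_100g"] / 100.0)
    energy = scored_energy + other_energy

    # exposure: score the simulated intakes (not a coin flip)
    pmds = score_pmds(intakes, cutoffs)
    low_pmds = (pmds["pmds_group"] == "low").to_numpy()

    # outcome risk: log-linear in exposure and covariate terms
    log_risk = np.full(n, np.log(cfg.baseline_risk))
    log_risk += np.log(cfg.true_rr_low_pmds) * low_pmds
    for cov, by_level in cfg.covariate_effects.items():
        lv = covariates[cov].to_numpy()
        for level, log_rr in by_level.items():
            log_risk += log_rr * (lv == level)
    risk = np.exp(log_risk)
    if (risk > 1.0).any():
        i = int(np.argmax(risk))
        stratum = {c: covariates[c].iloc[i] for c in cfg.covariate_effects}
        stratum["low_pmds"] = bool(low_pmds[i])
        raise ValueError(f"risk {risk[i]:.3f} > 1 in stratum {stratum}; "
                         "reduce baseline risk or covariate effects")
    latent = rng.random(n) < risk
    concordant = rng.random(n) < cfg.k6_concordance
    realized = np.where(concordant, latent, ~latent)
    k6 = _k6_items(rng, realized)

    table = pd.DataFrame({"participant_id": np.arange(1, n + 1)})
    # FFQ frequencies per day, derived from the component intakes
    for item, info in defaults.ITEM_CATALOG.items():
        source = info["group"] if info["group"] is not None else "other_foods"
        table[f"ffq_freq_{item}"] = (intakes[source] * info["weight"]
                                     / info["portion_g"]).to_numpy()
    for comp in FOOD_GROUPS + ["other_foods"]:
        table[comp] = intakes[comp].to_numpy()
    for comp in ("mufa_g", "sfa_g", "ethanol_g"):
        table[comp] = intakes[comp].to_numpy()
    table["energy_kcal"] = energy
    table = pd.concat([table, covariates], axis=1)
    for i, col in enumerate(K6_COLUMNS):
        table[col] = k6[:, i]

    flags = cfg.flag_rates
    table["first_participation"] = rng.random(n) >= flags.get("repeat_participation", 0.0)
    table["abortion_stillbirth"] = rng.random(n) < flags.get("abortion_stillbirth", 0.0)
    table["mental_illness_history"] = rng.random(n) < flags.get("mental_illness_history", 0.0)

    table["true_low_pmds"] = low_pmds
    table["true_risk"] = risk

    if cfg.missingness_rates:
        table = inject_missingness(table, cfg.missingness_rates,
                                   seed=int(rng.integers(0, 2**31 - 1)))
    return table


def inject_missingness(table: pd.DataFrame, rates: dict[str, float], seed: int) -> pd.DataFrame:
    """Set cells missing completely at random, per-column rate.

    Observed cells are unchanged; a rate of 0 returns the column intact
    and a rate of 1 blanks it entirely.
    """
    for col, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"missingness rate for {col} outside [0, 1]: {r}")
        if col not in table.columns:
            raise ValueError(f"unknown column {col!r}")
    rng = np.random.default_rng(seed)
    out = table.copy()
    for col, r in rates.items():
        if r == 0.0:
            continue
        mask = rng.random(len(out)) < r
        target = out[col]
        if target.dtype.kind in "iub":  # needs a NaN-capable dtype
            out[col] = target.astype(object)
        out.loc[mask, col] = np.nan
    return out


def ffq_long(raw: pd.DataFrame) -> pd.DataFrame:
    """Long-format FFQ records from a generated cohort table.

    One row per participant x catalog item with the frequency, portion
    size, and energy density the intake-arithmetic stage consumes.
    """
    frames = []
    for item, info in defaults.ITEM_CATALOG.items():
        col = f"ffq_freq_{item}"
        frames.append(pd.DataFrame({
            "participant_id": raw["participant_id"],
            "item_id": item,
            "frequency_per_day": raw[col],
            "portion_g": float(info["portion_g"]),
            "energy_per_100g": float(info["energy_per_100g"]),
        }))
    return pd.concat(frames, ignore_index=True)


def save_cohort(table: pd.DataFrame, path: str | Path, config: SimulationConfig) -> None:
    """Write the cohort CSV plus a provenance sidecar (seed and config)."""
    path = Path(path)
    table.to_csv(path, index=False)
    meta = dataclasses.asdict(config)
    meta.pop("cutoffs", None)
    meta.pop("intake_log_correlation", None)
    meta = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in meta.items()}
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(json.dumps(meta, indent=2, default=float) + "\n")


def simulate_binary_cohort(
    n: int,
    *,
    rr: float,
    baseline_risk: float,
    p_exposed: float,
    seed: int,
) -> pd.DataFrame:
    """Minimal exposure/outcome cohort for engine-calibration studies.

    Bernoulli exposure, Bernoulli outcome with risk baseline_risk * rr
    for the exposed.  Used for coverage simulations where the full
    FFQ-level generator would be wasteful.
    """
    if baseline_risk * max(rr, 1.0) > 1.0:
        raise ValueError("risk exceeds 1 in the exposed stratum")
    rng = np.random.default_rng(seed)
    exposed = (rng.random(n) < p_exposed).astype(int)
    risk = baseline_risk * np.where(exposed == 1, rr, 1.0)
    case = (rng.random(n) < risk).astype(int)
    return pd.DataFrame({"exposed": exposed, "case": case})
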