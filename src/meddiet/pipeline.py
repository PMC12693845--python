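"""End-to-end analysis orchestration.

One configuration drives: cohort input (synthetic draw or CSV) ->
intake arithmetic -> K6 scoring -> selection cascade -> diet scoring ->
covariate imputation -> crude/adjusted/joint risk-ratio models -> PAF
estimation, emitting baseline-characteristics, outcome-by-group,
RR and PAF report tables plus an attrition log.  Every artifact carries
the seed and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import defaults
from .ffq import aggregate_components
from .impute import ImputationSpec, impute
from .k6 import score_k6_frame
from .paf import paf_delta_ci
from .regression import ModelSpec, crude_rr_2x2, expand_2x2, fit_modified_poisson, pearson_chi2
from .scoring import CutoffTable, score_all
from .selection import DEFAULT_ENERGY_BOUNDS, apply_exclusions
from .simulate import K6_COLUMNS, SimulationConfig, ffq_long, generate_cohort

SCORES = ("mds", "rmed", "pmds")
JOINT_PAIRS = (("pmds", "mds"), ("pmds", "rmed"), ("mds", "rmed"))

__all__ = ["RunConfig", "run_pipeline", "crude_rr_from_counts"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    synthetic: SimulationConfig | None = None
    cohort_csv: str | None = None
    cutoffs: CutoffTable | None = None
    cutoffs_csv: str | None = None
    energy_bounds: tuple[float, float] = DEFAULT_ENERGY_BOUNDS
    adjustment_covariates: list[str] = field(default_factory=lambda: [
        "age_cat", "bmi_cat", "parity", "multiple_pregnancy", "conception_method",
        "dm_gdm", "alcohol_status", "smoking_maternal", "smoking_paternal",
        "marital_status", "employment", "edu_maternal", "edu_paternal",
        "income", "region", "mds_mt1"])
    impute_k: int = 5
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.cohort_csv is None):
            raise ValueError("exactly one input source: synthetic config or cohort CSV")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        syn = raw.pop("synthetic", None)
        cfg = cls(synthetic=SimulationConfig(**syn) if syn else None, **raw)
        return cfg

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("cutoffs", None)
        d.pop("out_dir", None)  # the hash identifies the analysis, not its destination
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _resolve_cutoffs(config: RunConfig) -> CutoffTable:
    if config.cutoffs is not None:
        return config.cutoffs
    if config.cutoffs_csv is not None:
        return CutoffTable.from_csv(config.cutoffs_csv)
    return defaults.default_cutoffs()


def _baseline_table(cohort: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Covariate level counts (percent) overall and by score group."""
    blocks = []
    strata = {"all": pd.Series(True, index=cohort.index)}
    for s in SCORES:
        for g in ("low", "high"):
            strata[f"{g}_{s}"] = cohort[f"{s}_group"] == g
    for cov in covariates:
        if cov not in cohort.columns:
            continue
        for level in pd.unique(cohort[cov].dropna()):
            row = {"covariate": cov, "level": level}
            for name, mask in strata.items():
                sub = cohort[mask]
                n = int((sub[cov] == level).sum())
                pct = 100.0 * n / len(sub) if len(sub) else np.nan
                row[f"{name}_n"] = n
                row[f"{name}_pct"] = round(pct, 2)
            blocks.append(row)
    return pd.DataFrame(blocks)


def _outcome_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """K6 category distribution by score group, with chi-square p per score."""
    rows = []
    cats = ["le4", "5to9", "10to12", "ge13"]
    for s in SCORES:
        low = cohort[cohort[f"{s}_group"] == "low"]
        high = cohort[cohort[f"{s}_group"] == "high"]
        counts = {"score": s}
        for cat in cats:
            counts[f"low_{cat}"] = int((low["k6_category"] == cat).sum())
            counts[f"high_{cat}"] = int((high["k6_category"] == cat).sum())
        tab = np.array([[counts["low_ge13"], len(low) - counts["low_ge13"]],
                        [counts["high_ge13"], len(high) - counts["high_ge13"]]])
        stat, _, p = pearson_chi2(tab)
        counts["chi2_distress"] = round(stat, 4)
        counts["p_distress"] = p
        rows.append(counts)
    return pd.DataFrame(rows)


def _fit_models(cohort: pd.DataFrame, config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Crude and adjusted RR + PAF per score, and joint two-score models."""
    covs = {c: defaults.COVARIATE_REFERENCES.get(c, None)
            for c in config.adjustment_covariates if c in cohort.columns}
    for c, ref in list(covs.items()):
        if ref is None or ref not in set(cohort[c].dropna()):
            covs[c] = cohort[c].mode().iloc[0]

    rr_rows, paf_rows = [], []
    for s in SCORES:
        exp_col = f"low_{s}"
        for model_name, covariates in (("crude", {}), ("adjusted", covs)):
            spec = ModelSpec(outcome="k6_distress01", exposures=[exp_col],
                             covariates=dict(covariates))
            fit = fit_modified_poisson(cohort, spec)
            rr, lo, hi = fit.rr(exp_col)
            rr_rows.append({"score": s, "model": model_name, "exposure": exp_col,
                            "rr": rr, "ci_lo": lo, "ci_hi": hi,
                            "rr_2dp": round(rr, 2), "ci_lo_2dp": round(lo, 2),
                            "ci_hi_2dp": round(hi, 2), "n": fit.n_used})
            paf = paf_delta_ci(fit, cohort, exp_col, outcome="k6_distress01")
            paf_rows.append({"score": s, "model": model_name, **paf.as_dict()})

    joint_rows = []
    for s1, s2 in JOINT_PAIRS:
        spec = ModelSpec(outcome="k6_distress01",
                         exposures=[f"low_{s1}", f"low_{s2}"], covariates=dict(covs))
        fit = fit_modified_poisson(cohort, spec)
        for s in (s1, s2):
            rr, lo, hi = fit.rr(f"low_{s}")
            paf = paf_delta_ci(fit, cohort, f"low_{s}", outcome="k6_distress01")
            joint_rows.append({"pair": f"{s1}+{s2}", "score": s, "rr": rr,
                               "ci_lo": lo, "ci_hi": hi,
                               "paf_percent": paf.paf_percent,
                               "paf_ci_lo": paf.ci95[0], "paf_ci_hi": paf.ci95[1]})
    rr_table = pd.concat([pd.DataFrame(rr_rows)], ignore_index=True)
    return rr_table.merge(pd.DataFrame(paf_rows)[
        ["score", "model", "paf_percent", "ci_lo", "ci_hi", "pe_cases_exposed"]]
        .rename(columns={"ci_lo": "paf_ci_lo", "ci_hi": "paf_ci_hi"}),
        on=["score", "model"]), pd.DataFrame(joint_rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; return the report bundle.

    The bundle maps artifact name to DataFrame (or the attrition log /
    metadata dict).  With ``config.out_dir`` set, every artifact is also
    written as TSV/JSON.
    """
    stage = "input"
    try:
        if config.synthetic is not None:
            raw = generate_cohort(config.synthetic)
        else:
            raw = pd.read_csv(config.cohort_csv)
        cutoffs = _resolve_cutoffs(config)

        stage = "intakes"
        long = ffq_long(raw)
        intakes = aggregate_components(long, defaults.default_item_mapping())
        keep = [c for c in raw.columns if not c.startswith("ffq_freq_")
                and c not in intakes.columns]
        cohort = raw[keep].merge(intakes.reset_index(), on="participant_id",
                                 suffixes=("", "_agg"))

        stage = "k6"
        k6 = score_k6_frame(cohort, K6_COLUMNS)
        cohort = pd.concat([cohort, k6], axis=1)

        stage = "selection"
        cohort, attrition = apply_exclusions(
            cohort, energy_bounds=config.energy_bounds,
            outcome_columns=["k6_total"],
            exposure_columns=[g for g in defaults.default_item_mapping().values()
                              if g in cohort.columns] + ["mufa_g", "sfa_g", "ethanol_g"])

        stage = "imputation"
        cov_cols = [c for c in config.adjustment_covariates if c in cohort.columns]
        if cov_cols and cohort[cov_cols].isna().any().any():
            spec = ImputationSpec(columns=cov_cols, k=config.impute_k, seed=config.seed)
            cohort, audit = impute(cohort.reset_index(drop=True), spec)
        else:
            audit = pd.DataFrame(columns=["row", "column", "imputed_value", "k"])

        stage = "scoring"
        scores = score_all(cohort, cutoffs)
        score_cols = [c for c in scores.columns if c != "participant_id"]
        cohort = pd.concat([cohort.reset_index(drop=True),
                            scores[score_cols].reset_index(drop=True)], axis=1)
        complete = cohort[[f"{s}_group" for s in SCORES]].notna().all(axis=1) \
            & cohort["k6_distress"].notna()
        cohort = cohort[complete].reset_index(drop=True)
        for s in SCORES:
            cohort[f"low_{s}"] = (cohort[f"{s}_group"] == "low").astype(int)
        cohort["k6_distress01"] = cohort["k6_distress"].astype(int)

        stage = "models"
        rr_table, joint_table = _fit_models(cohort, config)
        baseline = _baseline_table(cohort, config.adjustment_covariates)
        outcome = _outcome_table(cohort)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err

    meta = {"seed": config.seed, "config_hash": config.config_hash(),
            "n_analysis": int(len(cohort)),
            "n_imputed_cells": int(len(audit))}
    bundle = {"baseline_characteristics": baseline,
              "outcome_by_group": outcome,
              "rr_results": rr_table,
              "joint_results": joint_table,
              "attrition": attrition,
              "imputation_audit": audit,
              "analysis_cohort": cohort,
              "meta": meta}

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("baseline_characteristics", "outcome_by_group",
                     "rr_results", "joint_results", "imputation_audit"):
            bundle[name].to_csv(out / f"{name}.tsv", sep="\t", index=False,
                                float_format="%.10g")
        attrition.to_tsv(out / "attrition.tsv")
        (out / "attrition.txt").write_text(str(attrition) + "\n")
        (out / "rr_results.json").write_text(
            json.dumps(rr_table.to_dict(orient="records"), indent=2, default=float) + "\n")
        (out / "run_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return bundle


def crude_rr_from_counts(cases_exposed: int, n_exposed: int,
                         cases_unexposed: int, n_unexposed: int) -> dict:
    """Aggregate-input mode: crude RR via both estimation paths.

    Feeds printed 2x2 counts through the closed form and, expanded to
    individual rows, through the sandwich-Poisson regression.  The two
    must agree analytically.
    """
    closed = crude_rr_2x2(cases_exposed, n_exposed, cases_unexposed, n_unexposed)
    rows = expand_2x2(cases_exposed, n_exposed, cases_unexposed, n_unexposed)
    fit = fit_modified_poisson(rows, ModelSpec(outcome="case", exposures=["exposed"]))
    poisson = fit.rr("exposed")
    return {"closed_form": {"rr": closed[0], "ci_lo": closed[1], "ci_hi": closed[2]},
            "poisson": {"rr": poisson[0], "ci_lo": poisson[1], "ci_hi": poisson[2]},
            "rr_2dp": round(closed[0], 2),
            "ci_2dp": (round(closed[1], 2), round(closed[2], 2))}
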