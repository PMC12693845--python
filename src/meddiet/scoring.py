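"""Mediterranean-diet adherence indices: MDS, rMED and PMDS.

Three scores are computed from the wide component-intake table against a
cutoff table (external Mediterranean reference values or within-sample
quantiles):

* **MDS** — nine 0/1 components scored against medians.  Beneficial:
  vegetables, fruits+nuts, legumes, fish, cereals, and the MUFA/SFA
  ratio (1 point at or above the median).  Detrimental: dairy and meat
  (1 point below the median).  Alcohol: 1 point for 5-25 g/day ethanol.
  Range 0-9; high adherence >= 5.
* **rMED** — nine components scored 0/1/2 by intake tertile.
  Beneficial (ascending 0/1/2): vegetables, fruits+nuts, legumes, fish,
  cereals, olive oil (the fat component).  Detrimental (descending
  2/1/0): meat, dairy.  Alcohol: 2 points for 5-25 g/day ethanol, else
  0.  Range 0-18; high >= 11.
* **PMDS** — pregnancy variant of the MDS: alcohol and the fat ratio
  are dropped and dairy counts as beneficial.  Seven 0/1 components
  (vegetables, fruits+nuts, legumes, fish, cereals, dairy beneficial;
  meat detrimental).  Range 0-7; high >= 4.

Boundary conventions: a beneficial intake exactly at its median scores
1 ("at or above the median"); tertile intervals are lower-closed,
[0, t1) / [t1, t2) / [t2, inf); the alcohol window [5, 25] g/day is
closed at both ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ffq import FOOD_GROUPS

ALCOHOL_WINDOW = (5.0, 25.0)  # g/day ethanol

# Components scored against a median cutoff (fat_ratio = mufa_g/sfa_g).
MEDIAN_COMPONENTS = FOOD_GROUPS[:7] + ["fat_ratio"]  # excludes olive_oil
# Components scored by tertile for the rMED.
TERTILE_COMPONENTS = ["vegetables", "fruits_nuts", "legumes", "fish",
                      "cereals", "olive_oil", "meat", "dairy"]

MDS_BENEFICIAL = ["vegetables", "fruits_nuts", "legumes", "fish", "cereals", "fat_ratio"]
MDS_DETRIMENTAL = ["dairy", "meat"]
RMED_BENEFICIAL = ["vegetables", "fruits_nuts", "legumes", "fish", "cereals", "olive_oil"]
RMED_DETRIMENTAL = ["meat", "dairy"]
PMDS_BENEFICIAL = ["vegetables", "fruits_nuts", "legumes", "fish", "cereals", "dairy"]
PMDS_DETRIMENTAL = ["meat"]

HIGH_THRESHOLD = {"mds": 5, "rmed": 11, "pmds": 4}
SCORE_RANGE = {"mds": (0, 9), "rmed": (0, 18), "pmds": (0, 7)}

__all__ = [
    "CutoffTable", "score_mds", "score_rmed", "score_pmds", "score_all",
    "derive_cutoffs", "ALCOHOL_WINDOW", "HIGH_THRESHOLD", "SCORE_RANGE",
    "MDS_BENEFICIAL", "MDS_DETRIMENTAL", "RMED_BENEFICIAL", "RMED_DETRIMENTAL",
    "PMDS_BENEFICIAL", "PMDS_DETRIMENTAL", "MEDIAN_COMPONENTS", "TERTILE_COMPONENTS",
]


@dataclass
class CutoffTable:
    """Per-component cutoffs used by the three diet scores.

    ``medians`` maps component name (food groups and ``fat_ratio``) to
    its median cutoff; ``tertiles`` maps component name to the tertile
    bounds (t1, t2).  ``provenance`` records whether the cutoffs are an
    external reference (e.g. a Mediterranean source population) or were
    derived from the analysis sample itself.  ``sex`` allows optional
    sex-specific tables; an all-female pregnancy cohort uses a single
    set.
    """

    medians: dict[str, float] = field(default_factory=dict)
    tertiles: dict[str, tuple[float, float]] = field(default_factory=dict)
    alcohol_window: tuple[float, float] = ALCOHOL_WINDOW
    provenance: str = "external_reference"
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.provenance not in ("external_reference", "within_sample"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        for comp, m in self.medians.items():
            if m < 0:
                raise ValueError(f"negative median cutoff for {comp}")
        for comp, (t1, t2) in self.tertiles.items():
            if not 0 <= t1 <= t2:
                raise ValueError(f"invalid tertile bounds for {comp}: ({t1}, {t2})")
        lo, hi = self.alcohol_window
        if not 0 <= lo <= hi:
            raise ValueError("invalid alcohol window")

    def require(self, medians: list[str] = (), tertiles: list[str] = ()) -> None:
        miss_m = [c for c in medians if c not in self.medians]
        miss_t = [c for c in tertiles if c not in self.tertiles]
        if miss_m or miss_t:
            raise ValueError(f"cutoff table lacks medians for {miss_m} "
                             f"and tertile bounds for {miss_t}")

    def to_frame(self) -> pd.DataFrame:
        comps = sorted(set(self.medians) | set(self.tertiles))
        rows = []
        for c in comps:
            t = self.tertiles.get(c, (np.nan, np.nan))
            rows.append({"component": c, "median": self.medians.get(c, np.nan),
                         "t1": t[0], "t2": t[1], "sex": self.sex or ""})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, *, provenance: str = "external_reference") -> "CutoffTable":
        df = pd.read_csv(path)
        medians, tertiles = {}, {}
        for _, r in df.iterrows():
            if not np.isnan(r.get("median", np.nan)):
                medians[r["component"]] = float(r["median"])
            if not np.isnan(r.get("t1", np.nan)):
                tertiles[r["component"]] = (float(r["t1"]), float(r["t2"]))
        sex = None
        if "sex" in df.columns and df["sex"].astype(str).str.len().any():
            sex = str(df["sex"].iloc[0]) or None
        return cls(medians=medians, tertiles=tertiles, provenance=provenance, sex=sex)


def _with_fat_ratio(intakes: pd.DataFrame) -> pd.DataFrame:
    df = intakes.copy()
    if "fat_ratio" not in df.columns:
        sfa = df["sfa_g"].to_numpy(dtype=float)
        mufa = df["mufa_g"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(sfa > 0, mufa / sfa, np.nan)
        df["fat_ratio"] = ratio
    return df


def _missing_reason(df: pd.DataFrame, needed: list[str]) -> pd.Series:
    """First missing needed component per row, empty string if complete."""
    reason = pd.Series("", index=df.index, dtype=object)
    for comp in needed:
        vals = df[comp] if comp in df.columns else pd.Series(np.nan, index=df.index)
        miss = vals.isna() & (reason == "")
        code = "fat_ratio_undefined" if comp == "fat_ratio" else f"missing_{comp}"
        reason[miss] = code
    return reason


def _median_points(df, components, cutoffs, beneficial):
    pts = {}
    for comp in components:
        cut = cutoffs.medians[comp]
        at_or_above = df[comp].to_numpy(dtype=float) >= cut
        pts[comp] = np.where(at_or_above, 1, 0) if comp in beneficial \
            else np.where(at_or_above, 0, 1)
    return pts


def _tertile_points(values: np.ndarray, bounds: tuple[float, float], *, beneficial: bool) -> np.ndarray:
    t1, t2 = bounds
    # lower-closed tertile intervals: [0,t1), [t1,t2), [t2,inf)
    tert = np.where(values >= t2, 2, np.where(values >= t1, 1, 0))
    return tert if beneficial else 2 - tert


def _alcohol_in_window(ethanol: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (ethanol >= lo) & (ethanol <= hi)


def _assemble(df, pts, total, name, threshold, reason):
    out = pd.DataFrame(index=df.index)
    if "participant_id" in df.columns:
        out["participant_id"] = df["participant_id"]
    for comp, p in pts.items():
        out[f"{name}_{comp}"] = p
    valid = reason == ""
    out[f"{name}_points"] = pd.array(np.where(valid, total, np.nan), dtype="Int64")
    out[f"{name}_group"] = np.where(valid, np.where(total >= threshold, "high", "low"), None)
    out[f"{name}_exclusion_reason"] = reason
    return out


def score_mds(intakes: pd.DataFrame, cutoffs: CutoffTable) -> pd.DataFrame:
    """Nine-component MDS (0-9); high adherence at >= 5 points.

    Rows with any missing component (or an undefined fat ratio) get a
    missing score and an exclusion reason code.
    """
    cutoffs.require(medians=MEDIAN_COMPONENTS)
    df = _with_fat_ratio(intakes)
    needed = MDS_BENEFICIAL + MDS_DETRIMENTAL + ["ethanol_g"]
    reason = _missing_reason(df, needed)
    pts = _median_points(df, MDS_BENEFICIAL + MDS_DETRIMENTAL, cutoffs, set(MDS_BENEFICIAL))
    pts["alcohol"] = _alcohol_in_window(
        df["ethanol_g"].to_numpy(dtype=float), cutoffs.alcohol_window).astype(int)
    total = sum(pts.values())
    return _assemble(df, pts, total, "mds", HIGH_THRESHOLD["mds"], reason)


def score_rmed(intakes: pd.DataFrame, cutoffs: CutoffTable) -> pd.DataFrame:
    """Tertile-based rMED (0-18); high adherence at >= 11 points.

    Olive oil is the fat component; alcohol is scored 2 inside the
    5-25 g/day ethanol window and 0 outside.
    """
    cutoffs.require(tertiles=TERTILE_COMPONENTS)
    df = intakes
    needed = RMED_BENEFICIAL + RMED_DETRIMENTAL + ["ethanol_g"]
    reason = _missing_reason(df, needed)
    pts = {}
    for comp in RMED_BENEFICIAL:
        pts[comp] = _tertile_points(df[comp].to_numpy(dtype=float),
                                    cutoffs.tertiles[comp], beneficial=True)
    for comp in RMED_DETRIMENTAL:
        pts[comp] = _tertile_points(df[comp].to_numpy(dtype=float),
                                    cutoffs.tertiles[comp], beneficial=False)
    pts["alcohol"] = 2 * _alcohol_in_window(
        df["ethanol_g"].to_numpy(dtype=float), cutoffs.alcohol_window).astype(int)
    total = sum(pts.values())
    return _assemble(df, pts, total, "rmed", HIGH_THRESHOLD["rmed"], reason)


def score_pmds(intakes: pd.DataFrame, cutoffs: CutoffTable) -> pd.DataFrame:
    """Seven-component pregnancy MDS (0-7); high adherence at >= 4.

    Dairy is beneficial here (calcium needs rise in pregnancy) and the
    alcohol and fat-ratio components are dropped.
    """
    cutoffs.require(medians=PMDS_BENEFICIAL + PMDS_DETRIMENTAL)
    df = intakes
    needed = PMDS_BENEFICIAL + PMDS_DETRIMENTAL
    reason = _missing_reason(df, needed)
    pts = _median_points(df, PMDS_BENEFICIAL + PMDS_DETRIMENTAL, cutoffs, set(PMDS_BENEFICIAL))
    total = sum(pts.values())
    return _assemble(df, pts, total, "pmds", HIGH_THRESHOLD["pmds"], reason)


def score_all(intakes: pd.DataFrame, cutoffs: CutoffTable) -> pd.DataFrame:
    """All three scores side by side, one row per participant."""
    parts = [score_mds(intakes, cutoffs), score_rmed(intakes, cutoffs),
             score_pmds(intakes, cutoffs)]
    out = parts[0]
    for p in parts[1:]:
        cols = [c for c in p.columns if c not in out.columns]
        out = out.join(p[cols])
    return out


def derive_cutoffs(intakes: pd.DataFrame, scheme: str = "both") -> CutoffTable:
    """Within-sample cutoffs: component medians and/or tertile bounds.

    ``scheme`` is ``"median"``, ``"tertile"`` or ``"both"``.  Tertile
    bounds are the 1/3 and 2/3 linearly interpolated sample quantiles.
    A constant component yields t1 == t2 (all mass lands in the third
    tertile under the lower-closed boundary rule) with a warning.
    """
    if scheme not in ("median", "tertile", "both"):
        raise ValueError(f"unknown scheme {scheme!r}")
    df = _with_fat_ratio(intakes)
    medians, tertiles = {}, {}
    if scheme in ("median", "both"):
        for comp in MEDIAN_COMPONENTS:
            vals = df[comp].dropna().to_numpy(dtype=float)
            if len(vals) < 3:
                raise ValueError(f"need at least 3 observed values for {comp}")
            medians[comp] = float(np.median(vals))
    if scheme in ("tertile", "both"):
        for comp in TERTILE_COMPONENTS:
            vals = df[comp].dropna().to_numpy(dtype=float)
            if len(vals) < 3:
                raise ValueError(f"need at least 3 observed values for {comp}")
            t1, t2 = np.quantile(vals, [1 / 3, 2 / 3], method="linear")
            if t1 == t2:
                warnings.warn(f"degenerate tertile bounds for {comp} (constant "
                              "component); all mass scores as third tertile",
                              stacklevel=2)
            tertiles[comp] = (float(t1), float(t2))
    return CutoffTable(medians=medians, tertiles=tertiles, provenance="within_sample")
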