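"""Participant-selection cascade and attrition accounting.

Filters are applied in a fixed order — first participation only, no
abortion/stillbirth, complete and plausible exposure/outcome data,
energy intake inside the stated bounds (inclusive), no history of
mental illness — and every step is logged so alternative orderings are
auditable.  A participant triggering several criteria is attributed to
the first filter that catches them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

__all__ = ["AttritionLog", "apply_exclusions", "energy_sd_bounds", "DEFAULT_ENERGY_BOUNDS"]

# Realized +/-2 SD energy-intake window of the source analysis (kcal/day),
# accepted directly as configuration; energy_sd_bounds recomputes on new data.
DEFAULT_ENERGY_BOUNDS = (216.0, 3253.9)


@dataclass
class AttritionLog:
    """Ordered per-filter accounting of exclusions."""

    steps: list[tuple[str, int, int, int]] = field(default_factory=list)

    def record(self, name: str, n_before: int, n_excluded: int) -> None:
        self.steps.append((name, n_before, n_excluded, n_before - n_excluded))

    @property
    def n_final(self) -> int:
        return self.steps[-1][3] if self.steps else 0

    def validate(self) -> None:
        for i, (name, before, excl, after) in enumerate(self.steps):
            if after != before - excl:
                raise AssertionError(f"inconsistent counts at step {name}")
            if i and before != self.steps[i - 1][3]:
                raise AssertionError(f"broken chain before step {name}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps,
                            columns=["filter", "n_before", "n_excluded", "n_after"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __str__(self) -> str:
        lines = ["Participant selection:"]
        for name, before, excl, after in self.steps:
            lines.append(f"  {name}: {before} -> {after} (excluded {excl})")
        return "\n".join(lines)


REQUIRED_FLAGS = ["first_participation", "abortion_stillbirth", "mental_illness_history"]


def apply_exclusions(
    cohort: pd.DataFrame,
    *,
    energy_bounds: tuple[float, float] = DEFAULT_ENERGY_BOUNDS,
    outcome_columns: list[str] | None = None,
    exposure_columns: list[str] | None = None,
    improbable: Callable[[pd.DataFrame], pd.Series] | None = None,
) -> tuple[pd.DataFrame, AttritionLog]:
    """Apply the selection cascade; return (analysis cohort, log).

    Steps, in order:

    1. keep first participation only (``first_participation`` flag);
    2. drop abortion / stillbirth;
    3. drop rows with missing exposure/outcome data or flagged as
       improbable by the user-supplied predicate (default: none);
    4. drop energy intake outside ``energy_bounds`` (inclusive);
    5. drop history of mental illness.
    """
    missing_cols = [c for c in REQUIRED_FLAGS + ["energy_kcal"] if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort lacks required columns: {missing_cols}")

    log = AttritionLog()
    df = cohort

    keep = df["first_participation"].astype(bool)
    log.record("first_participation_only", len(df), int((~keep).sum()))
    df = df[keep]

    drop = df["abortion_stillbirth"].astype(bool)
    log.record("abortion_stillbirth", len(df), int(drop.sum()))
    df = df[~drop]

    check_cols = list(outcome_columns or []) + list(exposure_columns or [])
    bad = pd.Series(False, index=df.index)
    for c in check_cols:
        bad |= df[c].isna()
    if improbable is not None:
        bad |= improbable(df).astype(bool).reindex(df.index, fill_value=False)
    bad |= df["energy_kcal"].isna()
    log.record("missing_or_improbable_data", len(df), int(bad.sum()))
    df = df[~bad]

    lo, hi = energy_bounds
    energy = df["energy_kcal"].to_numpy(dtype=float)
    outside = (energy < lo) | (energy > hi)
    log.record("energy_outside_bounds", len(df), int(outside.sum()))
    df = df[~outside]

    drop = df["mental_illness_history"].astype(bool)
    log.record("mental_illness_history", len(df), int(drop.sum()))
    df = df[~drop]

    log.validate()
    return df.copy(), log


def energy_sd_bounds(energy: np.ndarray | pd.Series) -> tuple[float, float]:
    """Mean +/- 2 sample SD (ddof=1) of an energy-intake vector."""
    vals = np.asarray(pd.Series(energy).dropna(), dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 observations")
    m = vals.mean()
    sd = vals.std(ddof=1)
    return (float(m - 2 * sd), float(m + 2 * sd))
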