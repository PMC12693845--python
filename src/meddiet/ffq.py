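"""Food-frequency-questionnaire (FFQ) intake arithmetic.

Turns long-format FFQ responses (one row per participant x item, with a
daily intake frequency and a portion size in grams) into per-participant
daily food-group intakes (g/day), total energy (kcal/day), and the
component table the diet scores consume.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# Scored component fields of the wide intake table.
FOOD_GROUPS = ["vegetables", "fruits_nuts", "legumes", "fish", "cereals",
               "meat", "dairy", "olive_oil"]
FAT_FIELDS = ["mufa_g", "sfa_g"]
OTHER_FIELDS = ["ethanol_g", "energy_kcal"]
COMPONENT_FIELDS = FOOD_GROUPS + FAT_FIELDS + OTHER_FIELDS

__all__ = ["ComponentIntake", "daily_intake", "total_energy",
           "aggregate_components", "FOOD_GROUPS", "COMPONENT_FIELDS"]


@dataclass
class ComponentIntake:
    """Per-participant daily intakes of the scored components (g/day).

    ``missing_flags`` marks fields with no observed data rather than a
    true zero intake.
    """

    participant_id: object
    values: dict[str, float] = field(default_factory=dict)
    missing_flags: dict[str, bool] = field(default_factory=dict)

    def fat_ratio(self) -> float:
        """Monounsaturated-to-saturated fat ratio; NaN when undefined."""
        sfa = self.values.get("sfa_g", np.nan)
        mufa = self.values.get("mufa_g", np.nan)
        if not sfa or np.isnan(sfa) or np.isnan(mufa):
            return float("nan")
        return mufa / sfa


def daily_intake(frequency_per_day: float, portion_g: float) -> float:
    """Daily intake in g/day: intake frequency times portion size."""
    if frequency_per_day < 0 or portion_g < 0:
        raise ValueError("frequency and portion size must be non-negative")
    return frequency_per_day * portion_g


def total_energy(records: pd.DataFrame) -> float:
    """Total daily energy (kcal/day) for one participant's FFQ records.

    Each item contributes its energy density (kcal/100 g) times its
    daily amount.  A missing energy density flags the participant as
    energy-missing (NaN returned).  An empty record set warns and
    returns 0.
    """
    if len(records) == 0:
        warnings.warn("no FFQ records; total energy is 0", stacklevel=2)
        return 0.0
    e = records["energy_per_100g"].to_numpy(dtype=float)
    if np.isnan(e).any():
        return float("nan")
    amounts = records["frequency_per_day"].to_numpy(float) * records["portion_g"].to_numpy(float)
    if (amounts < 0).any() or (e < 0).any():
        raise ValueError("negative FFQ quantities")
    return float(np.sum(amounts * e / 100.0))


def aggregate_components(
    records: pd.DataFrame,
    item_to_group: dict[str, str],
) -> pd.DataFrame:
    """Aggregate long-format FFQ records into the wide component table.

    Parameters
    ----------
    records:
        Long format with columns ``participant_id``, ``item_id``,
        ``frequency_per_day``, ``portion_g`` and (optionally)
        ``energy_per_100g``.
    item_to_group:
        Mapping from item_id to food-group name.  Unmapped items are
        ignored (logged); a mapping to an unknown group raises.

    Returns a wide frame indexed by participant with one column per food
    group plus ``energy_kcal``, and boolean ``<group>_missing`` columns
    for groups with no mapped observed item.
    """
    unknown = set(item_to_group.values()) - set(FOOD_GROUPS)
    if unknown:
        raise ValueError(f"mapping references unknown food groups: {sorted(unknown)}")

    rec = records.copy()
    dup = rec.duplicated(["participant_id", "item_id"])
    if dup.any():
        raise ValueError("duplicate (participant_id, item_id) rows")
    if (rec["frequency_per_day"] < 0).any() or (rec["portion_g"] < 0).any():
        raise ValueError("negative FFQ quantities")

    rec["group"] = rec["item_id"].map(item_to_group)
    n_unmapped = int(rec["group"].isna().sum())
    if n_unmapped:
        log.info("ignoring %d FFQ rows whose items are not in the group mapping", n_unmapped)
    rec["amount"] = rec["frequency_per_day"] * rec["portion_g"]

    participants = pd.Index(rec["participant_id"].unique(), name="participant_id")
    mapped = rec.dropna(subset=["group"])
    wide = (mapped.pivot_table(index="participant_id", columns="group",
                               values="amount", aggfunc="sum")
            .reindex(index=participants))

    out = pd.DataFrame(index=participants)
    for g in FOOD_GROUPS:
        if g in wide.columns:
            out[g] = wide[g]
        else:
            out[g] = np.nan
        out[f"{g}_missing"] = out[g].isna()

    if "energy_per_100g" in rec.columns:
        energy = (rec.assign(kcal=rec["amount"] * rec["energy_per_100g"] / 100.0)
                  .groupby("participant_id")["kcal"]
                  .apply(lambda s: np.nan if s.isna().any() else s.sum())
                  .reindex(participants))
        out["energy_kcal"] = energy
        out["energy_missing"] = energy.isna()
    return out


def energy_adjust(intakes: pd.DataFrame, *, per_kcal: float = 1000.0) -> pd.DataFrame:
    """Optional energy adjustment: food-group intakes per ``per_kcal`` kcal.

    Leaves non-food-group columns untouched; requires ``energy_kcal``.
    """
    if "energy_kcal" not in intakes.columns:
        raise ValueError("energy adjustment requires an energy_kcal column")
    out = intakes.copy()
    scale = per_kcal / intakes["energy_kcal"]
    for g in FOOD_GROUPS:
        if g in out.columns:
            out[g] = out[g] * scale
    return out
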