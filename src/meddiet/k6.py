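"""Kessler 6-item Psychological Distress Scale (K6) scoring.

Six items, each answered 0-4, summed to a 0-24 total.  A total of 13 or
more defines psychological distress; totals are also binned into the
conventional reporting categories <=4, 5-9, 10-12, >=13.  Participants
with any missing item get a missing total (no prorating).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DISTRESS_CUTOFF = 13
N_ITEMS = 6
CATEGORIES = ("le4", "5to9", "10to12", "ge13")

__all__ = ["K6Response", "score_k6", "score_k6_frame", "DISTRESS_CUTOFF", "CATEGORIES"]


@dataclass(frozen=True)
class K6Response:
    items: tuple[int, ...]
    total: int
    category: str
    distress: bool


def _categorize(total: int) -> str:
    if total <= 4:
        return "le4"
    if total <= 9:
        return "5to9"
    if total <= 12:
        return "10to12"
    return "ge13"


def score_k6(items) -> K6Response:
    """Score one K6 response vector.

    Raises on the wrong item count or out-of-range values; a missing
    item (None/NaN) raises ``ValueError`` with reason ``k6_missing`` —
    frame-level scoring reason-codes those rows instead.
    """
    items = tuple(items)
    if len(items) != N_ITEMS:
        raise ValueError(f"K6 requires exactly {N_ITEMS} items, got {len(items)}")
    vals = []
    for v in items:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError("k6_missing: missing item response")
        iv = int(v)
        if iv != v or not 0 <= iv <= 4:
            raise ValueError(f"K6 item responses must be integers in [0, 4], got {v!r}")
        vals.append(iv)
    total = sum(vals)
    return K6Response(items=tuple(vals), total=total,
                      category=_categorize(total), distress=total >= DISTRESS_CUTOFF)


def score_k6_frame(table: pd.DataFrame, item_columns: list[str]) -> pd.DataFrame:
    """Score a cohort of K6 responses.

    Returns a frame with ``k6_total`` (nullable Int), ``k6_category``,
    ``k6_distress`` (nullable boolean) and ``k6_missing`` flag columns.
    Rows with any missing item are flagged and left missing.
    """
    if len(item_columns) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} item columns, got {len(item_columns)}")
    items = table[item_columns].to_numpy(dtype=float)
    out_of_range = np.nan_to_num(items, nan=0.0)
    if ((out_of_range < 0) | (out_of_range > 4)).any() or \
            (np.nan_to_num(items % 1, nan=0.0) != 0).any():
        raise ValueError("K6 item responses must be integers in [0, 4]")
    missing = np.isnan(items).any(axis=1)
    total = items.sum(axis=1)
    result = pd.DataFrame(index=table.index)
    result["k6_total"] = pd.array(np.where(missing, np.nan, total), dtype="Int64")
    result["k6_category"] = [None if m else _categorize(int(t))
                             for m, t in zip(missing, total)]
    result["k6_distress"] = pd.array(
        np.where(missing, None, total >= DISTRESS_CUTOFF), dtype="boolean")
    result["k6_missing"] = missing
    return result
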