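"""Single k-nearest-neighbour imputation of categorical covariates.

Missing covariate cells are filled with the modal value among the k
nearest complete donor rows.  Distance is Hamming on categorical
features and range-scaled absolute difference on ordinal codes (a Gower
mix).  Outcome and exposure columns are never imputed.  Determinism:
neighbour-distance ties are broken by a seeded random permutation fixed
before search, modal-vote ties by first-seen category among the
neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ImputationSpec", "impute"]


@dataclass
class ImputationSpec:
    columns: list[str]
    k: int = 5
    ordinal_columns: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        extra = set(self.ordinal_columns) - set(self.columns)
        if extra:
            raise ValueError(f"ordinal columns not in feature list: {sorted(extra)}")


def _encode(table: pd.DataFrame, spec: ImputationSpec):
    """Numeric feature matrix: ordinal codes range-scaled to [0,1], NaN kept."""
    mats, kinds = [], []
    for col in spec.columns:
        s = table[col]
        if col in spec.ordinal_columns:
            vals = s.to_numpy(dtype=float)
            rng_ = np.nanmax(vals) - np.nanmin(vals)
            vals = (vals - np.nanmin(vals)) / rng_ if rng_ > 0 else np.zeros_like(vals)
            mats.append(vals)
            kinds.append("ordinal")
        else:
            codes = pd.Categorical(s).codes.astype(float)
            codes[codes < 0] = np.nan
            mats.append(codes)
            kinds.append("categorical")
    return np.column_stack(mats), kinds


def impute(table: pd.DataFrame, spec: ImputationSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing cells in ``spec.columns``; observed cells unchanged.

    Returns ``(completed table, audit)`` where the audit lists one row
    per imputed cell (row index, column, imputed value, k used).

    Neighbour search for a row with a missing cell in column c uses the
    remaining feature columns observed in that row; donors must be
    complete in those features and in c.  Distances are averaged over
    the usable features.
    """
    X, kinds = _encode(table, spec)
    n, p = X.shape
    rng = np.random.default_rng(spec.seed)
    tie_order = rng.permutation(n)  # seeded tie-break among equidistant donors

    col_index = {c: j for j, c in enumerate(spec.columns)}
    missing_mask = pd.DataFrame({c: table[c].isna() for c in spec.columns})
    rows_all_missing = missing_mask.all(axis=1)
    if rows_all_missing.any():
        raise ValueError(f"{int(rows_all_missing.sum())} row(s) missing every "
                         "distance feature; cannot locate neighbours")

    out = table.copy()
    audit_rows = []
    any_missing = missing_mask.any(axis=1).to_numpy()
    for i in np.flatnonzero(any_missing):
        observed_feats = np.flatnonzero(~np.isnan(X[i]))
        for c in spec.columns:
            j = col_index[c]
            if not np.isnan(X[i, j]):
                continue
            feats = observed_feats
            donors = np.flatnonzero(
                ~np.isnan(X[:, j]) & ~np.isnan(X[:, feats]).any(axis=1))
            donors = donors[donors != i]
            if len(donors) < spec.k:
                raise ValueError(f"only {len(donors)} complete donors for cell "
                                 f"(row {table.index[i]}, column {c}); k={spec.k}")
            diffs = np.empty((len(donors), len(feats)))
            for a, f in enumerate(feats):
                if kinds[f] == "ordinal":
                    diffs[:, a] = np.abs(X[donors, f] - X[i, f])
                else:
                    diffs[:, a] = (X[donors, f] != X[i, f]).astype(float)
            dist = diffs.mean(axis=1)
            # sort by (distance, seeded order) for deterministic ties
            order = np.lexsort((tie_order[donors], dist))
            nearest = donors[order[: spec.k]]
            votes = table[c].iloc[nearest]
            winner = _modal_first_seen(votes)
            out.iat[i, out.columns.get_loc(c)] = winner
            audit_rows.append({"row": table.index[i], "column": c,
                               "imputed_value": winner, "k": spec.k})

    audit = pd.DataFrame(audit_rows, columns=["row", "column", "imputed_value", "k"])
    return out, audit


def _modal_first_seen(votes: pd.Series):
    """Modal value; ties broken by first appearance among the neighbours."""
    counts: dict = {}
    for v in votes:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    for v in votes:  # first-seen order
        if counts[v] == best:
            return v
    raise AssertionError("unreachable")
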