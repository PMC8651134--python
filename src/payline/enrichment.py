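"""Joining practice characteristics onto linked payments.

Builds one profile row per payment-receiving practice — total value, payment
and company counts, region, list size, share of patients over 65, deprivation
decile — and assigns the quartile groupings used for stratified comparison:
practice size, elderly share, and deprivation (quartile 1 = most deprived).

Quartiles are computed over the payment-receiving practices only (the
analysis population), with type-7 quantile cut points and ties assigned to
the lower quartile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["assign_quartiles", "profile_practices", "GROUPINGS"]

GROUPINGS = ("region", "size_quartile", "elderly_quartile", "imd_quartile")


def assign_quartiles(values) -> np.ndarray:
    """Quartile labels 1..4 from type-7 quantile cut points.

    Label k is the smallest k with value <= cutpoint_k (cut points at the
    0.25/0.50/0.75 type-7 quantiles); values above the third cut point get 4.
    With heavy ties, whole quartiles can collapse downward (all-equal input
    is labelled 1 throughout).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot assign quartiles to an empty sequence")
    cuts = np.quantile(v, [0.25, 0.50, 0.75])  # numpy default = type 7
    return (1 + (v[:, None] > cuts[None, :]).sum(axis=1)).astype(int)


def profile_practices(linked: pd.DataFrame, registry: pd.DataFrame) -> pd.DataFrame:
    """One row per payment-receiving practice, with aggregates and strata.

    Raises if any linked practice code is missing from the registry.  The sum
    of profile totals equals the linked-value total to the penny.
    """
    paid = linked[linked["practice_code"].notna()]
    if paid.empty:
        raise ValueError("no linked payments to profile")
    codes = set(registry["practice_code"])
    missing = sorted(set(paid["practice_code"]) - codes)
    if missing:
        raise ValueError(f"linked practice codes absent from registry: {missing[:10]}")

    pence = np.rint(paid["amount_gbp"].to_numpy() * 100).astype(np.int64)
    agg = (
        paid.assign(_pence=pence)
        .groupby("practice_code")
        .agg(
            total_pence=("_pence", "sum"),
            n_payments=("company", "size"),
            n_companies=("company", "nunique"),
        )
        .reset_index()
    )
    agg["total_value_gbp"] = agg.pop("total_pence") / 100.0

    prof = agg.merge(registry, on="practice_code", how="left", validate="1:1")
    prof["share_over_65"] = prof["n_over65"] / prof["n_registered"]
    prof["size_quartile"] = assign_quartiles(prof["n_registered"])
    prof["elderly_quartile"] = assign_quartiles(prof["share_over_65"])
    prof["imd_quartile"] = assign_quartiles(prof["imd_decile"])
    cols = [
        "practice_code", "region", "n_registered", "share_over_65", "imd_decile",
        "size_quartile", "elderly_quartile", "imd_quartile",
        "total_value_gbp", "n_payments", "n_companies",
    ]
    return prof[cols]
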