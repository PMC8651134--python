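"""Concentration descriptives: summary quartiles, per-entity profiles,
top-k donor/recipient shares and category breakdowns.

Payment values in this setting are heavily right-skewed, so location is
summarised by median and interquartile range (type-7 quantiles throughout).
Concentration is expressed as the share of total value (or payment count)
amassed by the top-k companies or practices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStats",
    "summarize",
    "concentration",
    "top_k_share",
    "category_breakdown",
    "summary_table",
]

CATEGORIES = ("donation_grant", "event_contribution", "service_consultancy")


@dataclass(frozen=True)
class SummaryStats:
    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float

    def as_row(self) -> dict:
        return {
            "n": self.n, "min": self.min, "q1": self.q1,
            "median": self.median, "q3": self.q3, "max": self.max,
        }


def summarize(values) -> SummaryStats:
    """Five-number summary with type-7 quartiles; exact on integer inputs."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sequence")
    q1, med, q3 = np.quantile(v, [0.25, 0.50, 0.75])
    return SummaryStats(
        n=int(v.size), min=float(v.min()), q1=float(q1),
        median=float(med), q3=float(q3), max=float(v.max()),
    )


def concentration(linked: pd.DataFrame, axis: str = "company") -> pd.DataFrame:
    """Per-entity payment profile, ranked by descending total value.

    ``axis`` is ``company`` (counterparties = distinct practices paid) or
    ``practice`` (counterparties = distinct paying companies).  Ties in total
    value rank lexicographically by entity name for a deterministic table.
    """
    if axis not in {"company", "practice"}:
        raise ValueError(f"axis must be company or practice, got {axis!r}")
    paid = linked[linked["practice_code"].notna()] if "practice_code" in linked else linked
    if paid.empty:
        raise ValueError("no linked payments")
    entity, counterpart = (
        ("company", "practice_code") if axis == "company" else ("practice_code", "company")
    )
    pence = np.rint(paid["amount_gbp"].to_numpy() * 100).astype(np.int64)
    g = paid.assign(_pence=pence).groupby(entity)
    out = g.agg(
        total_pence=("_pence", "sum"),
        n_payments=("amount_gbp", "size"),
        n_counterparties=(counterpart, "nunique"),
        median_single_payment=("amount_gbp", "median"),
        q1=("amount_gbp", lambda s: float(np.quantile(s, 0.25))),
        q3=("amount_gbp", lambda s: float(np.quantile(s, 0.75))),
    ).reset_index()
    out["total_value_gbp"] = out.pop("total_pence") / 100.0
    out = out.sort_values(
        ["total_value_gbp", entity], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out.insert(1, "rank", np.arange(1, len(out) + 1))
    cols = [entity, "rank", "total_value_gbp", "n_payments", "n_counterparties",
            "median_single_payment", "q1", "q3"]
    return out[cols]


def top_k_share(
    conc: pd.DataFrame,
    k: int,
    basis: str = "value",
    denominator: float | None = None,
) -> float:
    """Share of the denominator amassed by the top-k ranked entities.

    Ranking is always by total value (the published top-10 tables rank by
    value even when counting payments); ``basis`` selects whether the top-k
    figure summed is total value or payment count.  ``denominator`` defaults
    to the table's own grand total on the chosen basis.
    """
    if not 1 <= k <= len(conc):
        raise ValueError(f"k={k} out of range 1..{len(conc)}")
    col = {"value": "total_value_gbp", "count": "n_payments"}.get(basis)
    if col is None:
        raise ValueError(f"basis must be value or count, got {basis!r}")
    top = conc.nsmallest(k, "rank")[col].sum()
    denom = float(conc[col].sum()) if denominator is None else float(denominator)
    if denom <= 0:
        raise ValueError("denominator must be positive")
    return float(top) / denom


def category_breakdown(
    linked: pd.DataFrame, scope: str | None = None, weight: str = "value"
) -> dict[str, float]:
    """Fraction of payments per transfer-of-value category.

    Value-weighted by default (published breakdowns report value shares);
    ``weight='count'`` gives payment-count fractions.  ``scope`` restricts to
    one company.  Fractions sum to 1 within 1e-9.
    """
    df = linked if scope is None else linked[linked["company"] == scope]
    if df.empty:
        raise ValueError(f"no payments in scope {scope!r}")
    if weight == "value":
        totals = df.groupby("category")["amount_gbp"].sum()
    elif weight == "count":
        totals = df.groupby("category").size().astype(float)
    else:
        raise ValueError(f"weight must be value or count, got {weight!r}")
    frac = totals / totals.sum()
    return {c: float(frac.get(c, 0.0)) for c in CATEGORIES}


def summary_table(linked: pd.DataFrame) -> pd.DataFrame:
    """Overall summary rows: the seven published levels of analysis.

    Single payment values, per-practice and per-company value/count
    aggregates, practices per company and companies per practice.
    """
    paid = linked[linked["practice_code"].notna()]
    by_practice = concentration(paid, "practice")
    by_company = concentration(paid, "company")
    rows = {
        "single_payment_value_gbp": summarize(paid["amount_gbp"]),
        "value_per_practice_gbp": summarize(by_practice["total_value_gbp"]),
        "payments_per_practice": summarize(by_practice["n_payments"]),
        "value_per_company_gbp": summarize(by_company["total_value_gbp"]),
        "payments_per_company": summarize(by_company["n_payments"]),
        "practices_per_company": summarize(by_company["n_counterparties"]),
        "companies_per_practice": summarize(by_practice["n_counterparties"]),
    }
    return pd.DataFrame({k: s.as_row() for k, s in rows.items()}).T.reset_index(
        names="level_of_analysis"
    )
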