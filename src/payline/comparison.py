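"""Stratified nonparametric comparison of per-practice payment values.

Each stratum of a practice characteristic (region, size quartile, elderly
quartile, deprivation quartile) is compared against a stated reference
stratum with a two-sided Wilcoxon rank-sum (Mann-Whitney) test on the
per-practice total payment value.  Raw p-values are reported per stratum
with no multiplicity adjustment, significance flagged at alpha = 0.05.

The test statistic is U = R_x - n_x(n_x+1)/2 with midranks for ties.  Exact
mode enumerates the permutation null and is only valid without ties; the
normal approximation uses the tie-corrected variance and a 0.5 continuity
correction.  ``auto`` picks exact when n_x + n_y <= 20 and the pooled sample
is tie-free.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = ["rank_sum_test", "stratified_comparison", "DEFAULT_REFERENCES"]

DEFAULT_REFERENCES = {
    "region": "London",
    "size_quartile": 1,
    "elderly_quartile": 1,
    "imd_quartile": 1,
}

_EXACT_MAX_N = 20


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def rank_sum_test(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (U of x, p-value).

    ``mode``: ``exact`` (permutation null, rejects tied data), the
    tie-corrected continuity-corrected ``normal_approx``, or ``auto``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    ties = _has_ties(np.concatenate([x, y]))
    if mode == "exact":
        if ties:
            raise ValueError(
                "exact mode is invalid with tied observations; use normal_approx"
            )
        method = "exact"
    elif mode == "normal_approx":
        method = "asymptotic"
    elif mode == "auto":
        method = "exact" if (x.size + y.size <= _EXACT_MAX_N and not ties) else "asymptotic"
    else:
        raise ValueError(f"mode must be exact, normal_approx or auto, got {mode!r}")
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def stratified_comparison(
    profiles: pd.DataFrame,
    grouping: str,
    reference_label=None,
    alpha: float = 0.05,
    mode: str = "auto",
    unit: str = "practice",
    linked: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-stratum medians/IQRs and rank-sum p-values against the reference.

    The unit of analysis is the per-practice total value (default) or, with
    ``unit='payment'`` and a linked table, the individual payment value.
    The reference row carries a null p-value and ``is_reference`` True.
    """
    if grouping not in profiles.columns:
        raise ValueError(f"unknown grouping {grouping!r}")
    if reference_label is None:
        reference_label = DEFAULT_REFERENCES.get(grouping)
        if reference_label is None:
            raise ValueError(f"no default reference for grouping {grouping!r}")

    if unit == "practice":
        data = profiles[[grouping, "total_value_gbp"]].rename(
            columns={"total_value_gbp": "value"}
        )
    elif unit == "payment":
        if linked is None:
            raise ValueError("unit='payment' requires the linked payment table")
        paid = linked[linked["practice_code"].notna()]
        data = paid.merge(
            profiles[["practice_code", grouping]], on="practice_code", how="left"
        )[[grouping, "amount_gbp"]].rename(columns={"amount_gbp": "value"})
    else:
        raise ValueError(f"unit must be practice or payment, got {unit!r}")

    strata = sorted(data[grouping].unique(), key=lambda s: (s != reference_label, s))
    if reference_label not in set(strata):
        raise ValueError(f"reference stratum {reference_label!r} is empty or unknown")
    ref_values = data.loc[data[grouping] == reference_label, "value"].to_numpy()

    rows = []
    for label in strata:
        values = data.loc[data[grouping] == label, "value"].to_numpy()
        q1, med, q3 = np.quantile(values, [0.25, 0.50, 0.75])
        is_ref = label == reference_label
        if is_ref:
            p = np.nan
        else:
            _, p = rank_sum_test(values, ref_values, mode=mode)
        rows.append(
            {
                "grouping": grouping,
                "stratum": label,
                "n_practices": int(values.size),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "p_value": p,
                "significant": (not is_ref) and bool(p < alpha),
                "is_reference": is_ref,
            }
        )
    return pd.DataFrame(rows)
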