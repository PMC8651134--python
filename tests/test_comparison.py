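"""Rank-sum test contract and stratified comparison behaviour.

The exact-mode oracle enumerates every assignment of pooled ranks to the
first sample and computes the two-sided tail probability of U directly.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from payline import rank_sum_test, stratified_comparison


def brute_force_exact_p(x, y):
    """Two-sided permutation p for untied samples by full enumeration."""
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1
    nx, ny = len(x), len(y)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    mid = nx * ny / 2
    hits = total = 0
    for comb in combinations(range(nx + ny), nx):
        u = sum(sorted(ranks)[i] for i in comb) - nx * (nx + 1) / 2
        total += 1
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            hits += 1
    return u_obs, hits / total


def test_exact_two_and_two():
    u, p = rank_sum_test([1, 2], [3, 4], mode="exact")
    assert u == 0
    assert p == pytest.approx(1 / 3)  # 2 of the 6 rank assignments are as extreme


def test_exact_three_and_three():
    u, p = rank_sum_test([1, 3, 5], [2, 4, 6], mode="exact")
    assert u == 3
    assert p == pytest.approx(0.70)  # 14 of the 20 assignments


@pytest.mark.parametrize("seed", range(6))
def test_exact_mode_agrees_with_enumeration(seed):
    rng = np.random.default_rng(seed)
    nx, ny = rng.integers(2, 7, size=2)
    pooled = rng.permutation(np.arange(1.0, nx + ny + 1))  # untied by construction
    x, y = pooled[:nx], pooled[nx:]
    u_ref, p_ref = brute_force_exact_p(x, y)
    u, p = rank_sum_test(x, y, mode="exact")
    assert u == pytest.approx(u_ref)
    assert p == pytest.approx(p_ref, abs=1e-12)


def test_p_is_symmetric_in_the_samples():
    rng = np.random.default_rng(4)
    x, y = rng.normal(size=15), rng.normal(1.0, 1, size=12)
    for mode in ("normal_approx", "auto"):
        assert rank_sum_test(x, y, mode)[1] == pytest.approx(rank_sum_test(y, x, mode)[1])


def test_exact_mode_rejects_ties():
    with pytest.raises(ValueError, match="normal_approx"):
        rank_sum_test([1, 1, 2], [3, 4], mode="exact")


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        rank_sum_test([], [1, 2])


def test_exact_and_normal_agree_for_moderate_untied_samples():
    """The approximation error bound that justifies mode='auto'."""
    rng = np.random.default_rng(8)
    for n in (10, 11, 12):
        for _ in range(20):
            pooled = rng.permutation(np.arange(1.0, 2 * n + 1))
            x, y = pooled[:n], pooled[n:]
            _, p_exact = rank_sum_test(x, y, mode="exact")
            _, p_norm = rank_sum_test(x, y, mode="normal_approx")
            assert abs(p_exact - p_norm) <= 0.02


def test_type_one_error_calibrated_at_alpha():
    """Null rejection rate at alpha=0.05 stays within 0.05 +/- 0.02."""
    rng = np.random.default_rng(12)
    n_rep, n = 1200, 25
    rejections = 0
    for _ in range(n_rep):
        x, y = rng.normal(size=n), rng.normal(size=n)
        _, p = rank_sum_test(x, y, mode="normal_approx")
        rejections += p < 0.05
    assert 0.03 <= rejections / n_rep <= 0.07


def _profiles(values_by_stratum, grouping="size_quartile"):
    rows = []
    for label, values in values_by_stratum.items():
        for i, v in enumerate(values):
            rows.append({"practice_code": f"{label}-{i}", grouping: label,
                         "total_value_gbp": float(v)})
    return pd.DataFrame(rows)


def test_identical_strata_are_not_significant():
    values = np.linspace(100, 5000, 50)
    prof = _profiles({1: values, 2: values})
    out = stratified_comparison(prof, "size_quartile", reference_label=1)
    p = out.loc[out["stratum"] == 2, "p_value"].item()
    assert p > 0.99
    assert not out.loc[out["stratum"] == 2, "significant"].item()


def test_reference_row_has_null_p():
    prof = _profiles({1: [1, 2, 3, 4], 2: [5, 6, 7, 8]})
    out = stratified_comparison(prof, "size_quartile", reference_label=1)
    ref = out[out["is_reference"]]
    assert len(ref) == 1 and ref["stratum"].item() == 1
    assert np.isnan(ref["p_value"].item())
    assert out["is_reference"].sum() == 1


def test_unknown_grouping_or_reference_rejected(profiles_default):
    with pytest.raises(ValueError, match="grouping"):
        stratified_comparison(profiles_default, "astrology_sign")
    with pytest.raises(ValueError, match="reference"):
        stratified_comparison(profiles_default, "region", reference_label="Narnia")


def test_shifted_stratum_detected_with_high_power():
    """A x3 value shift in quartile 4 yields p < 0.001 in >=95% of replicates."""
    rng = np.random.default_rng(99)
    n, hits, n_rep = 200, 0, 100
    for _ in range(n_rep):
        strata = {q: rng.lognormal(6.0, 1.2, size=n) for q in (1, 2, 3)}
        strata[4] = 3.0 * rng.lognormal(6.0, 1.2, size=n)
        out = stratified_comparison(_profiles(strata), "size_quartile",
                                    reference_label=1)
        hits += out.loc[out["stratum"] == 4, "p_value"].item() < 0.001
    assert hits >= 95


def test_per_payment_unit_variant(linked_default, profiles_default):
    linked, _ = linked_default
    out = stratified_comparison(profiles_default, "imd_quartile",
                                unit="payment", linked=linked)
    assert len(out) == 4
    assert out["n_practices"].sum() == linked["practice_code"].notna().sum()


def test_default_references_match_study_design(profiles_default):
    regional = stratified_comparison(profiles_default, "region")
    assert regional.loc[regional["is_reference"], "stratum"].item() == "London"
    for grouping in ("size_quartile", "elderly_quartile", "imd_quartile"):
        out = stratified_comparison(profiles_default, grouping)
        assert out.loc[out["is_reference"], "stratum"].item() == 1
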