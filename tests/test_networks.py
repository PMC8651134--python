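"""Incidence thresholds, one-mode projection, and valued graph statistics.

The projection oracle recomputes every edge weight by brute-force set
intersection of each company pair's active practices.
"""

import numpy as np
import pandas as pd
import pytest

from payline import (
    CompanyNetwork,
    ThresholdSpec,
    build_incidence,
    centralization,
    network_stats,
    project,
    strength_and_degree,
    stratified_networks,
    valued_density,
)
from payline.networks import to_networkx, write_edgelist


def _linked(rows):
    return pd.DataFrame(rows, columns=["company", "practice_code", "amount_gbp"])


def _net(companies, weights):
    w = np.asarray(weights)
    assert (w == w.T).all()
    return CompanyNetwork(list(companies), w, ThresholdSpec())


PAIR = _linked([["i", "p", 50.0], ["i", "p", 150.0]])


class TestThresholds:
    def test_single_payment_basis(self):
        inc = build_incidence(PAIR, ThresholdSpec("single_payment_value", 100.0))
        assert inc.pairs["active"].all()

    def test_basis_distinction_at_200(self):
        single = build_incidence(PAIR, ThresholdSpec("single_payment_value", 200.0))
        total = build_incidence(PAIR, ThresholdSpec("pair_total_value", 200.0))
        assert not single.pairs["active"].any()
        assert total.pairs["active"].all()

    def test_zero_cutoff_keeps_every_paid_pair(self):
        inc = build_incidence(PAIR, ThresholdSpec("single_payment_value", 0.0))
        assert inc.pairs["active"].all()

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSpec("single_payment_value", -1.0)
        with pytest.raises(ValueError):
            ThresholdSpec("weird_basis", 1.0)


class TestProjection:
    def test_one_shared_practice(self):
        linked = _linked([["A", "p1", 1], ["A", "p2", 1], ["B", "p2", 1], ["B", "p3", 1]])
        net = project(build_incidence(linked))
        assert net.weights[net.companies.index("A"), net.companies.index("B")] == 1

    def test_disjoint_companies_are_retained_isolates(self):
        linked = _linked([["A", "p1", 1], ["B", "p2", 1]])
        stats = network_stats(project(build_incidence(linked)))
        assert stats.n_nodes == 2
        assert stats.n_isolates == 2

    def test_matches_brute_force_on_random_small_incidences(self):
        """Exhaustive set-intersection oracle over all shapes up to 6x8."""
        rng = np.random.default_rng(17)
        for n_c in range(1, 7):
            for n_p in range(1, 9):
                for _ in range(4):
                    mask = rng.random((n_c, n_p)) < 0.45
                    rows = [
                        [f"c{i}", f"p{j}", 1.0]
                        for i in range(n_c) for j in range(n_p) if mask[i, j]
                    ]
                    if not rows:
                        continue
                    net = project(build_incidence(_linked(rows)))
                    sets = {
                        c: {r[1] for r in rows if r[0] == c} for c in net.companies
                    }
                    for a, ca in enumerate(net.companies):
                        assert net.weights[a, a] == 0
                        for b, cb in enumerate(net.companies):
                            if a != b:
                                assert net.weights[a, b] == len(sets[ca] & sets[cb])
                                assert net.weights[a, b] == net.weights[b, a]

    def test_strengths_satisfy_handshake_identity(self, linked_default):
        linked, _ = linked_default
        net = project(build_incidence(linked))
        sd = strength_and_degree(net)
        assert sd["strength"].sum() == net.weights.sum()
        assert sd["strength"].sum() == 2 * np.triu(net.weights).sum()


class TestGraphStatistics:
    def test_density_uniform(self):
        net = _net("abc", [[0, 2, 2], [2, 0, 2], [2, 2, 0]])
        assert valued_density(net) == 2.0

    def test_density_single_edge(self):
        net = _net("abc", [[0, 1, 0], [1, 0, 0], [0, 0, 0]])
        assert valued_density(net) == pytest.approx(1 / 3)

    def test_density_needs_two_nodes(self):
        with pytest.raises(ValueError):
            valued_density(_net("a", [[0]]))

    def test_star_is_maximally_centralized(self):
        net = _net("abcd", [[0, 1, 1, 1], [1, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0, 0]])
        assert centralization(net, "valued") == 1.0
        assert centralization(net, "binary") == 1.0

    def test_complete_equal_weight_is_uncentralized(self):
        net = _net("abcd", 3 * (np.ones((4, 4)) - np.eye(4)))
        assert centralization(net, "valued") == 0.0
        assert centralization(net, "binary") == 0.0

    def test_three_node_path_hand_computation(self):
        # strengths (2, 3, 1), w_max 2, denominator (2)(1)(2) = 4, sum of
        # differences 0 + 1 + 2 = 3
        net = _net("abc", [[0, 2, 0], [2, 0, 1], [0, 1, 0]])
        assert centralization(net, "valued") == pytest.approx(3 / 4)

    def test_valued_equals_binary_when_weights_uniform(self):
        rng = np.random.default_rng(23)
        a = (rng.random((6, 6)) < 0.5).astype(int)
        w = np.triu(a, 1) * 3
        net = _net("abcdef", w + w.T)
        if net.weights.max() > 0:
            assert centralization(net, "valued") == pytest.approx(
                centralization(net, "binary"))

    def test_all_zero_network_scores_zero(self):
        net = _net("abc", np.zeros((3, 3), dtype=int))
        assert centralization(net, "valued") == 0.0

    def test_centralization_needs_three_nodes(self):
        with pytest.raises(ValueError):
            centralization(_net("ab", [[0, 1], [1, 0]]))


def test_threshold_monotonicity(linked_default):
    """Raising the cutoff never increases weights, nodes, or density."""
    linked, _ = linked_default
    prev = None
    for cutoff in (0.0, 100.0, 1000.0, 2500.0):
        net = project(build_incidence(linked, ThresholdSpec("single_payment_value", cutoff)))
        stats = network_stats(net)
        cur = (stats.n_nodes, net.weights.sum(), stats.valued_density or 0.0)
        if prev is not None:
            assert cur[0] <= prev[0]
            assert cur[1] <= prev[1]
            assert cur[2] <= prev[2]
        # shared counts never exceed either company's active practice count
        inc = build_incidence(linked, ThresholdSpec("single_payment_value", cutoff))
        active_counts = inc.active_pairs.groupby("company")["practice_code"].nunique()
        for i, a in enumerate(net.companies):
            for j, b in enumerate(net.companies):
                if i < j:
                    assert net.weights[i, j] <= min(active_counts[a], active_counts[b])
        prev = cur


def test_valued_centralization_bounded(linked_default):
    linked, _ = linked_default
    for cutoff in (0.0, 500.0):
        net = project(build_incidence(linked, ThresholdSpec("single_payment_value", cutoff)))
        if net.n_nodes >= 3:
            assert 0.0 <= centralization(net, "valued") <= 1.0


def test_dominant_donor_has_maximum_strength(default_bundle, linked_default):
    linked, _ = linked_default
    dominant = default_bundle.payments["company"].value_counts().idxmax()
    sd = strength_and_degree(project(build_incidence(linked))).set_index("company")
    assert sd["strength"].idxmax() == dominant


def test_stratified_networks_partition_the_active_pairs(linked_default, profiles_default):
    linked, _ = linked_default
    spec = ThresholdSpec("single_payment_value", 0.0)
    full = build_incidence(linked, spec)
    full_pairs = set(map(tuple, full.active_pairs[["company", "practice_code"]].to_numpy()))
    union = set()
    for _, (net, stats) in stratified_networks(linked, profiles_default, spec,
                                               "size_quartile").items():
        assert stats.n_nodes == net.n_nodes
    for label in sorted(profiles_default["size_quartile"].unique()):
        codes = set(profiles_default.loc[
            profiles_default["size_quartile"] == label, "practice_code"])
        sub = linked[linked["practice_code"].isin(codes)]
        union |= set(map(tuple, build_incidence(sub, spec)
                         .active_pairs[["company", "practice_code"]].to_numpy()))
    assert union == full_pairs


def test_degenerate_stratum_yields_undefined_stats_without_crash():
    linked = _linked([["A", "p1", 10.0]])
    profiles = pd.DataFrame({"practice_code": ["p1"], "size_quartile": [1]})
    out = stratified_networks(linked, profiles, ThresholdSpec(), "size_quartile")
    net, stats = out[1]
    assert stats.n_nodes == 1
    assert stats.valued_density is None
    assert stats.valued_centralization is None


def test_exports_roundtrip(tmp_path, linked_default):
    linked, _ = linked_default
    net = project(build_incidence(linked, ThresholdSpec("single_payment_value", 1000.0)))
    g = to_networkx(net)
    assert g.number_of_nodes() == net.n_nodes
    write_edgelist(net, tmp_path / "edges.csv")
    edges = pd.read_csv(tmp_path / "edges.csv")
    assert edges["shared_practices"].sum() == np.triu(net.weights).sum()
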