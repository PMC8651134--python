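"""Valued company networks from shared payment recipients.

Companies are connected when they pay the same practices: the company x
practice incidence (thresholded on single-payment value, pair total value,
or pair payment count) is projected one-mode onto a symmetric valued company
network whose edge weight counts the shared active practices.

Graph statistics follow the conventions of classical social-network
analysis of valued affiliation data:

* node *strength* (sum of edge weights) and binary *degree* (count of
  positive-weight ties);
* *valued density* — the sum of shared-practice counts over all unordered
  company pairs divided by the number of possible pairs, i.e. the mean tie
  strength per possible connection;
* *centralization* — the ratio of the observed sum of (max - node)
  centrality differences to the maximum attainable sum.  For the valued
  variant the normalizer is (n-1)(n-2) * w_max with w_max the largest
  observed edge weight, which reduces exactly to Freeman degree
  centralization on binary graphs and reaches 1 on a uniform-weight star.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ThresholdSpec",
    "BipartiteIncidence",
    "CompanyNetwork",
    "NetworkStats",
    "build_incidence",
    "project",
    "strength_and_degree",
    "valued_density",
    "centralization",
    "network_stats",
    "stratified_networks",
    "to_networkx",
    "write_graphml",
    "write_edgelist",
]

_BASES = ("single_payment_value", "pair_total_value", "pair_payment_count")


@dataclass(frozen=True)
class ThresholdSpec:
    """Rule deciding which company-practice pairs count as connections."""

    basis: str = "single_payment_value"
    cutoff: float = 0.0

    def __post_init__(self) -> None:
        if self.basis not in _BASES:
            raise ValueError(f"basis must be one of {_BASES}, got {self.basis!r}")
        if self.cutoff < 0:
            raise ValueError("cutoff must be nonnegative")

    def label(self) -> str:
        cut = int(self.cutoff) if float(self.cutoff).is_integer() else self.cutoff
        return f"{self.basis}_ge_{cut}"


@dataclass
class BipartiteIncidence:
    """Thresholded company x practice structure."""

    pairs: pd.DataFrame  # company, practice_code, n_payments, total_value_gbp, max_single, active
    threshold: ThresholdSpec
    stratum: str | None = None

    @property
    def active_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["active"]]


@dataclass
class CompanyNetwork:
    """Symmetric valued company graph; weights count shared practices."""

    companies: list[str]
    weights: np.ndarray  # (n, n) int, zero diagonal
    threshold: ThresholdSpec
    stratum: str | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.companies)


@dataclass
class NetworkStats:
    n_nodes: int
    n_isolates: int
    valued_density: float | None
    valued_centralization: float | None
    binary_centralization: float | None
    strength: dict[str, float] = field(default_factory=dict)
    degree: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_isolates": self.n_isolates,
            "valued_density": self.valued_density,
            "valued_centralization": self.valued_centralization,
            "binary_centralization": self.binary_centralization,
            "strength": self.strength,
            "degree": self.degree,
        }


def build_incidence(
    linked: pd.DataFrame,
    spec: ThresholdSpec = ThresholdSpec(),
    stratum: str | None = None,
) -> BipartiteIncidence:
    """Aggregate linked payments to company-practice pairs and apply the threshold.

    A pair is active iff it has at least one single payment >= cutoff
    (``single_payment_value``), a pair total >= cutoff (``pair_total_value``),
    or a payment count >= cutoff (``pair_payment_count``).
    """
    paid = linked[linked["practice_code"].notna()]
    if paid.empty:
        raise ValueError("no linked payments to build an incidence from")
    pairs = (
        paid.groupby(["company", "practice_code"])
        .agg(
            n_payments=("amount_gbp", "size"),
            total_value_gbp=("amount_gbp", "sum"),
            max_single=("amount_gbp", "max"),
        )
        .reset_index()
    )
    if spec.basis == "single_payment_value":
        active = pairs["max_single"] >= spec.cutoff
    elif spec.basis == "pair_total_value":
        active = pairs["total_value_gbp"] >= spec.cutoff
    else:
        active = pairs["n_payments"] >= spec.cutoff
    pairs["active"] = active
    return BipartiteIncidence(pairs=pairs, threshold=spec, stratum=stratum)


def project(incidence: BipartiteIncidence) -> CompanyNetwork:
    """One-mode projection: w_ij = number of practices active for both i and j.

    Nodes are companies with at least one active pair; companies sharing no
    practice with anyone remain as isolates.
    """
    act = incidence.active_pairs
    companies = sorted(act["company"].unique())
    if not companies:
        return CompanyNetwork([], np.zeros((0, 0), dtype=int),
                              incidence.threshold, incidence.stratum)
    a = pd.crosstab(
        act["company"], act["practice_code"]
    ).reindex(index=companies).to_numpy()
    a = (a > 0).astype(int)
    w = a @ a.T
    np.fill_diagonal(w, 0)
    return CompanyNetwork(companies, w, incidence.threshold, incidence.stratum)


def strength_and_degree(net: CompanyNetwork) -> pd.DataFrame:
    """Per-company strength (sum of weights) and binary degree."""
    w = net.weights
    return pd.DataFrame(
        {
            "company": net.companies,
            "strength": w.sum(axis=1),
            "degree": (w > 0).sum(axis=1),
        }
    )


def valued_density(net: CompanyNetwork) -> float:
    """Mean shared-practice count per unordered company pair."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    total = net.weights.sum() / 2  # each unordered pair counted once
    return float(total / (n * (n - 1) / 2))


def centralization(net: CompanyNetwork, mode: str = "valued") -> float:
    """Degree/strength centralization in [0, 1].

    ``valued``: sum of (max strength - strength) over nodes, normalized by
    (n-1)(n-2)*w_max.  ``binary``: Freeman degree centralization of the
    dichotomized graph.  An all-zero network scores 0 by convention.
    """
    n = net.n_nodes
    if n < 3:
        raise ValueError("centralization requires at least 3 nodes")
    w = net.weights
    if w.max() == 0:
        return 0.0
    if mode == "valued":
        c = w.sum(axis=1).astype(float)
        denom = (n - 1) * (n - 2) * float(w.max())
    elif mode == "binary":
        c = (w > 0).sum(axis=1).astype(float)
        denom = (n - 1) * (n - 2)
    else:
        raise ValueError(f"mode must be valued or binary, got {mode!r}")
    return float((c.max() - c).sum() / denom)


def network_stats(net: CompanyNetwork) -> NetworkStats:
    """All graph statistics, with undefined ones set to None (no crash)."""
    sd = strength_and_degree(net) if net.n_nodes else pd.DataFrame(
        columns=["company", "strength", "degree"]
    )
    return NetworkStats(
        n_nodes=net.n_nodes,
        n_isolates=int((sd["degree"] == 0).sum()) if net.n_nodes else 0,
        valued_density=valued_density(net) if net.n_nodes >= 2 else None,
        valued_centralization=centralization(net, "valued") if net.n_nodes >= 3 else None,
        binary_centralization=centralization(net, "binary") if net.n_nodes >= 3 else None,
        strength={c: float(s) for c, s in zip(sd["company"], sd["strength"])},
        degree={c: int(d) for c, d in zip(sd["company"], sd["degree"])},
    )


def stratified_networks(
    linked: pd.DataFrame,
    profiles: pd.DataFrame,
    spec: ThresholdSpec,
    grouping: str,
) -> dict:
    """One (network, stats) per stratum of a practice characteristic.

    Practices are filtered to the stratum *before* incidence construction, so
    the union of active pairs over strata equals the unstratified active set.
    """
    if grouping not in profiles.columns:
        raise ValueError(f"unknown grouping {grouping!r}")
    out = {}
    for label in sorted(profiles[grouping].unique(), key=str):
        codes = set(profiles.loc[profiles[grouping] == label, "practice_code"])
        sub = linked[linked["practice_code"].isin(codes)]
        if sub.empty:
            net = CompanyNetwork([], np.zeros((0, 0), dtype=int), spec, str(label))
        else:
            net = project(build_incidence(sub, spec, stratum=str(label)))
        out[label] = (net, network_stats(net))
    return out


# --------------------------------------------------------------------------
# export


def to_networkx(net: CompanyNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.companies)
    n = net.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            if net.weights[i, j] > 0:
                g.add_edge(
                    net.companies[i], net.companies[j],
                    shared_practices=int(net.weights[i, j]),
                )
    return g


def write_graphml(net: CompanyNetwork, path) -> None:
    nx.write_graphml(to_networkx(net), path)


def write_edgelist(net: CompanyNetwork, path) -> None:
    rows = [
        (net.companies[i], net.companies[j], int(net.weights[i, j]))
        for i in range(net.n_nodes)
        for j in range(i + 1, net.n_nodes)
        if net.weights[i, j] > 0
    ]
    pd.DataFrame(rows, columns=["company_a", "company_b", "shared_practices"]).to_csv(
        path, index=False
    )
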