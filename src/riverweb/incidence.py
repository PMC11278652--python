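"""Observed-vs-random (O/R) phylum-pair incidence and keystone taxa.

O is the percentage of network edges joining a given (unordered) phylum
pair. R is the percentage expected if the same number of edges were placed
uniformly at random among the network's N nodes: with n1 and n2 nodes in
the two phyla, R = 100·n1·n2/C(N,2) for distinct phyla and
100·C(n1,2)/C(N,2) within a phylum. O/R > 1 means the two phyla co-occur
more often than chance. Keystone taxa are nodes with high degree and low
unnormalized betweenness centrality.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "incidence_from_counts",
    "phylum_pair_incidence",
    "filter_incidence_report",
    "identify_keystones",
    "node_domain_fractions",
    "KeystoneReport",
]

INCIDENCE_COLUMNS = (
    "phylum_1", "phylum_2", "n1", "n2", "edge_count", "O", "R", "ratio"
)


def incidence_from_counts(
    n1: int, n2: int, edge_count: int, n_total: int, m_total: int,
    intra: bool | None = None,
) -> tuple[float, float, float]:
    """(O%, R%, O/R) for one phylum pair from node/edge counts alone.

    ``intra`` defaults to ``n1 == n2`` being insufficient information, so
    pass it explicitly when the two phyla happen to have equal node counts.
    The ratio is computed on the unrounded percentages.
    """
    if m_total < 1 or n_total < 2:
        raise ValidationError("need a network with >= 2 nodes and >= 1 edge")
    if intra is None:
        intra = n1 == n2
    possible = n_total * (n_total - 1) / 2
    pairs = n1 * (n1 - 1) / 2 if intra else n1 * n2
    if pairs < 1:
        raise ValidationError("phylum pair admits no node pair")
    o_pct = 100.0 * edge_count / m_total
    r_pct = 100.0 * pairs / possible
    return o_pct, r_pct, o_pct / r_pct


def phylum_pair_incidence(net: nx.Graph) -> pd.DataFrame:
    """One row per unordered phylum pair with at least one possible node pair.

    Columns: phylum_1, phylum_2 (phylum_1 <= phylum_2; equal for
    intra-phylum rows), n1, n2 node counts, edge_count, O and R in percent,
    and the O/R ratio computed on the unrounded percentages. Zero-edge rows
    are retained with O = 0; summed over all rows, O and R each total 100%.
    """
    n_total = net.number_of_nodes()
    m_total = net.number_of_edges()
    if n_total < 2 or m_total < 1:
        raise ValidationError("incidence needs >= 2 nodes and >= 1 edge")
    phyla = {}
    for node, data in net.nodes(data=True):
        ph = data.get("phylum")
        if not ph:
            raise ValidationError(f"node {node!r} has no phylum label")
        phyla[node] = ph
    counts = pd.Series(phyla).value_counts().to_dict()

    edge_counts: dict[tuple[str, str], int] = {}
    for u, v in net.edges:
        key = tuple(sorted((phyla[u], phyla[v])))
        edge_counts[key] = edge_counts.get(key, 0) + 1

    possible = n_total * (n_total - 1) / 2
    names = sorted(counts)
    rows = []
    for i, p1 in enumerate(names):
        for p2 in names[i:]:
            n1, n2 = counts[p1], counts[p2]
            if p1 == p2:
                pairs = n1 * (n1 - 1) / 2
            else:
                pairs = n1 * n2
            if pairs < 1:
                continue
            e = edge_counts.get((p1, p2), 0)
            o_pct = 100.0 * e / m_total
            r_pct = 100.0 * pairs / possible
            rows.append({
                "phylum_1": p1, "phylum_2": p2, "n1": n1, "n2": n2,
                "edge_count": e, "O": o_pct, "R": r_pct,
                "ratio": o_pct / r_pct,
            })
    return pd.DataFrame(rows, columns=list(INCIDENCE_COLUMNS))


def filter_incidence_report(
    rows: pd.DataFrame, o_cutoff: float = 0.5, ratio_cutoff: float = 1.0
) -> pd.DataFrame:
    """Report rows with O > o_cutoff (%) and O/R > ratio_cutoff, both strict.

    Intra-phylum rows come first, then inter-phylum, each block alphabetical
    — the conventional layout for these incidence tables.
    """
    kept = rows[(rows["O"] > o_cutoff) & (rows["ratio"] > ratio_cutoff)].copy()
    kept["_intra"] = (kept["phylum_1"] != kept["phylum_2"]).astype(int)
    kept = kept.sort_values(["_intra", "phylum_1", "phylum_2"]).drop(columns="_intra")
    return kept.reset_index(drop=True)


@dataclass(frozen=True)
class KeystoneReport:
    """Per-node centralities with keystone flags plus per-phylum aggregates.

    ``nodes`` columns: domain, phylum, degree, betweenness, mean_abundance,
    keystone. ``phylum_summary`` (keystones only): n_keystones,
    abundance_sum, plus that sum as a fraction of the keystone total and of
    the whole network total (both reported because either normalization is
    defensible).
    """

    nodes: pd.DataFrame
    phylum_summary: pd.DataFrame
    n_keystones: int
    n_nodes: int


def identify_keystones(
    net: nx.Graph,
    degree_cutoff: float = 100.0,
    betweenness_cutoff: float = 5000.0,
) -> KeystoneReport:
    """Keystone iff degree > degree_cutoff and betweenness < betweenness_cutoff.

    Both inequalities are strict; betweenness is exact, unweighted and
    unnormalized. An empty keystone set is a valid outcome and still yields
    a complete report.
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("keystones of an empty graph")
    btw = nx.betweenness_centrality(net, normalized=False)
    recs = []
    for node, data in net.nodes(data=True):
        deg = net.degree(node)
        b = btw[node]
        recs.append({
            "otu_id": node,
            "domain": data.get("domain", ""),
            "phylum": data.get("phylum", ""),
            "degree": deg,
            "betweenness": b,
            "mean_abundance": data.get("mean_abundance", np.nan),
            "keystone": bool(deg > degree_cutoff and b < betweenness_cutoff),
        })
    nodes = pd.DataFrame.from_records(recs).set_index("otu_id")
    ks = nodes[nodes["keystone"]]
    network_ab = nodes["mean_abundance"].sum()
    keystone_ab = ks["mean_abundance"].sum()
    if len(ks):
        summary = (
            ks.groupby("phylum")
            .agg(n_keystones=("keystone", "size"),
                 abundance_sum=("mean_abundance", "sum"))
            .sort_values("n_keystones", ascending=False)
        )
        summary["fraction_of_keystone_abundance"] = (
            summary["abundance_sum"] / keystone_ab if keystone_ab > 0 else np.nan
        )
        summary["fraction_of_network_abundance"] = (
            summary["abundance_sum"] / network_ab if network_ab > 0 else np.nan
        )
    else:
        summary = pd.DataFrame(
            columns=["n_keystones", "abundance_sum",
                     "fraction_of_keystone_abundance",
                     "fraction_of_network_abundance"]
        )
    return KeystoneReport(
        nodes=nodes,
        phylum_summary=summary,
        n_keystones=int(nodes["keystone"].sum()),
        n_nodes=len(nodes),
    )


def node_domain_fractions(net: nx.Graph) -> tuple[float, float]:
    """(bacterial %, archaeal %) of network nodes; sums to 100."""
    if net.number_of_nodes() == 0:
        raise ValidationError("domain fractions of an empty graph")
    domains = []
    for node, data in net.nodes(data=True):
        dom = data.get("domain")
        if dom not in ("Bacteria", "Archaea"):
            raise ValidationError(f"node {node!r} lacks a valid domain label")
        domains.append(dom)
    n = len(domains)
    bact = 100.0 * sum(d == "Bacteria" for d in domains) / n
    return bact, 100.0 - bact
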