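"""The twelve network-level topological features and per-sample subnetworks.

Feature set (fixed): node count, edge count, graph density, transitivity,
average clustering coefficient (CC), average degree, degree centralization
(Freeman), average nearest-neighbor degree, average path length (APL, over
connected pairs), average betweenness centrality (unnormalized), modularity
(MD, seeded Louvain) and degree assortativity. Features undefined on a
degenerate graph are reported missing (None), never coerced to 0.

Per-sample subnetworks are presence-induced: the subgraph of the network on
the OTUs with nonzero abundance in that sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_community
from scipy import stats

from .errors import ValidationError
from .nulls import average_path_length
from .tables import OtuTable, SampleMetadata

__all__ = [
    "TopologyFeatures",
    "FEATURE_NAMES",
    "compute_topology",
    "degree_centralization",
    "extract_sample_subnetwork",
    "per_sample_topology",
    "group_difference_tests",
    "significance_stars",
]


@dataclass(frozen=True)
class TopologyFeatures:
    node_count: float
    edge_count: float | None = None
    graph_density: float | None = None
    transitivity: float | None = None
    avg_clustering: float | None = None
    avg_degree: float | None = None
    degree_centralization: float | None = None
    avg_nearest_neighbor_degree: float | None = None
    avg_path_length: float | None = None
    avg_betweenness: float | None = None
    modularity: float | None = None
    assortativity: float | None = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


FEATURE_NAMES = tuple(f.name for f in fields(TopologyFeatures))


def degree_centralization(graph: nx.Graph) -> float | None:
    """Freeman degree centralization Σ(k_max − k_i) / ((n−1)(n−2)).

    1 for a star, 0 for any regular graph; undefined (None) below 3 nodes.
    """
    n = graph.number_of_nodes()
    if n < 3:
        return None
    degs = np.array([d for _, d in graph.degree()], dtype=float)
    return float((degs.max() - degs).sum() / ((n - 1) * (n - 2)))


def compute_topology(graph: nx.Graph, seed: int = 0) -> TopologyFeatures:
    """All twelve features of a simple undirected graph."""
    n = graph.number_of_nodes()
    if n == 0:
        raise ValidationError("topology of an empty graph")
    if n == 1:
        return TopologyFeatures(node_count=1)
    m = graph.number_of_edges()
    density = 2.0 * m / (n * (n - 1))
    avg_degree = 2.0 * m / n

    transitivity = nx.transitivity(graph) if m else None
    avg_clustering = nx.average_clustering(graph) if m else None

    annd_map = nx.average_neighbor_degree(graph)
    annd_vals = [annd_map[v] for v in graph if graph.degree(v) > 0]
    annd = float(np.mean(annd_vals)) if annd_vals else None

    apl = average_path_length(graph)
    btw = nx.betweenness_centrality(graph, normalized=False)
    avg_btw = float(np.mean(list(btw.values()))) if m else None

    if m:
        comms = nx_community.louvain_communities(graph, weight=None, seed=seed)
        md = nx_community.modularity(graph, comms, weight=None)
    else:
        md = None

    assort = None
    if m:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                a = nx.degree_assortativity_coefficient(graph)
                if np.isfinite(a):
                    assort = float(a)
            except (ValueError, ZeroDivisionError):
                assort = None

    return TopologyFeatures(
        node_count=float(n),
        edge_count=float(m),
        graph_density=density,
        transitivity=transitivity,
        avg_clustering=avg_clustering,
        avg_degree=avg_degree,
        degree_centralization=degree_centralization(graph),
        avg_nearest_neighbor_degree=annd,
        avg_path_length=apl,
        avg_betweenness=avg_btw,
        modularity=md,
        assortativity=assort,
    )


def extract_sample_subnetwork(net: nx.Graph, table: OtuTable, sample_id: str) -> nx.Graph:
    """Induced subgraph on network OTUs with abundance > 0 in the sample."""
    if sample_id not in table.data.index:
        raise ValidationError(f"unknown sample {sample_id!r}")
    row = table.data.loc[sample_id]
    present = {o for o in net.nodes if o in row.index and row[o] > 0}
    return nx.Graph(net.subgraph(present))


def per_sample_topology(
    net: nx.Graph,
    table: OtuTable,
    metadata: SampleMetadata | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One row of the 12 features per sample, annotated with season/landform/region."""
    rows = {}
    for sid in table.sample_ids:
        sub = extract_sample_subnetwork(net, table, sid)
        if sub.number_of_nodes() == 0:
            rows[sid] = {name: np.nan for name in FEATURE_NAMES}
            rows[sid]["node_count"] = 0.0
        else:
            feats = compute_topology(sub, seed=seed).as_dict()
            rows[sid] = {
                k: (np.nan if v is None else v) for k, v in feats.items()
            }
    df = pd.DataFrame.from_dict(rows, orient="index").loc[table.sample_ids]
    if metadata is not None:
        for col in ("season", "landform", "region"):
            df[col] = metadata.data[col].reindex(df.index)
    return df


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_difference_tests(
    feature_matrix: pd.DataFrame, grouping: pd.Series
) -> pd.DataFrame:
    """Two-group Wilcoxon rank-sum / multi-group one-way ANOVA per feature.

    The rank-sum test uses the tie-corrected normal approximation. Any group
    with fewer than 3 samples flags the comparison instead of computing it.
    Returns a DataFrame with columns feature, test, statistic, p, stars,
    flagged.
    """
    grouping = grouping.reindex(feature_matrix.index)
    levels = [lv for lv in pd.unique(grouping.dropna())]
    if len(levels) < 2:
        raise ValidationError("need at least 2 groups")
    numeric = feature_matrix.select_dtypes(include=[np.number])
    records = []
    for feat in numeric.columns:
        samples = [
            numeric.loc[grouping == lv, feat].dropna().to_numpy() for lv in levels
        ]
        if any(len(s) < 3 for s in samples):
            records.append(
                dict(feature=feat, test="", statistic=np.nan, p=np.nan,
                     stars="", flagged=True)
            )
            continue
        if len(levels) == 2:
            pooled = np.concatenate(samples)
            if np.all(pooled == pooled[0]):
                stat, p = np.nan, 1.0  # zero tie-corrected variance
            else:
                res = stats.mannwhitneyu(
                    samples[0], samples[1], alternative="two-sided",
                    method="asymptotic",
                )
                stat, p = float(res.statistic), float(res.pvalue)
            test = "wilcoxon-rank-sum"
        else:
            f = stats.f_oneway(*samples)
            stat, p = float(f.statistic), float(f.pvalue)
            test = "one-way-anova"
        records.append(
            dict(feature=feat, test=test, statistic=stat, p=p,
                 stars=significance_stars(p), flagged=False)
        )
    return pd.DataFrame.from_records(records)
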