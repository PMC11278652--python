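"""Co-occurrence network construction.

An OTU table is reduced to prevalent taxa, all pairwise Spearman rank
correlations are computed, p-values are Benjamini–Hochberg adjusted once
over every tested pair, and an undirected network is drawn with an edge for
every strong (rho > 0.6, positive only) and significant (q < 0.01)
correlation. Louvain community detection then assigns module ids.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_community
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ValidationError
from .tables import OtuTable, RunConfig, SampleMetadata, TaxonomyMap

logger = logging.getLogger("riverweb")

__all__ = [
    "filter_by_prevalence",
    "spearman_correlations",
    "benjamini_hochberg",
    "build_network",
    "detect_modules",
    "renormalize_by_domain",
    "build_cooccurrence_network",
]


def filter_by_prevalence(table: OtuTable, min_fraction: float = 0.30) -> OtuTable:
    """Keep OTUs present (abundance > 0) in at least ``min_fraction`` of samples.

    The comparison is inclusive: presence/n_samples >= min_fraction retains
    the OTU. Sample set is unchanged.
    """
    if not 0 < min_fraction <= 1:
        raise ConfigurationError("min_fraction must be in (0, 1]")
    if table.n_samples == 0:
        raise ValidationError("OTU table has no samples")
    presence = (table.values > 0).sum(axis=0) / table.n_samples
    keep = presence >= min_fraction
    return OtuTable(table.data.loc[:, keep])


def spearman_correlations(table: OtuTable) -> pd.DataFrame:
    """All pairwise Spearman correlations with BH-adjusted q-values.

    Returns a DataFrame with one row per unordered OTU pair (otu_i < otu_j
    in column order): ``rho`` from tie-corrected average ranks, two-sided
    ``p`` from the large-sample t approximation on n-2 degrees of freedom,
    and ``q`` adjusted once over all tested pairs. Pairs involving a
    constant OTU vector have undefined rho and are excluded (count logged).
    """
    n, k = table.values.shape
    if n < 5:
        raise ValidationError("need at least 5 samples for the t approximation")
    if k < 2:
        raise ValidationError("need at least 2 OTUs")
    vals = table.values
    constant = vals.max(axis=0) == vals.min(axis=0)
    n_const = int(constant.sum())
    if n_const:
        logger.info("excluding %d constant OTU vector(s) from correlation", n_const)
    ids = np.array(table.otu_ids)[~constant]
    sub = vals[:, ~constant]
    if sub.shape[1] < 2:
        raise ValidationError("fewer than 2 non-constant OTUs")
    ranks = stats.rankdata(sub, axis=0)  # average ranks, tie-corrected
    rho = np.corrcoef(ranks, rowvar=False)
    iu, ju = np.triu_indices(len(ids), k=1)
    r = np.clip(rho[iu, ju], -1.0, 1.0)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p[np.isnan(p)] = 0.0  # |rho| == 1 exactly
    out = pd.DataFrame(
        {"otu_i": ids[iu], "otu_j": ids[ju], "rho": r, "p": p}
    )
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_network(
    correlations: pd.DataFrame,
    taxonomy: TaxonomyMap,
    table: OtuTable,
    rho_threshold: float = 0.6,
    q_threshold: float = 0.01,
    use_absolute: bool = False,
    scope: str = "both",
) -> nx.Graph:
    """Draw the thresholded co-occurrence network.

    An edge requires rho > rho_threshold (strict; positive correlations only
    unless ``use_absolute``) and q < q_threshold (strict). Nodes are the
    OTUs incident to at least one edge; isolated OTUs are dropped, matching
    what a drawn network contains. Node attributes carry domain, phylum and
    mean relative abundance over the scope's samples.
    """
    strength = correlations["rho"].abs() if use_absolute else correlations["rho"]
    mask = (strength > rho_threshold) & (correlations["q"] < q_threshold)
    edges = correlations.loc[mask]
    logger.info(
        "build_network: %d of %d correlations pass thresholds",
        len(edges), len(correlations),
    )
    g = nx.Graph(scope=scope)
    g.add_edges_from(
        (row.otu_i, row.otu_j, {"rho": float(row.rho)})
        for row in edges.itertuples(index=False)
    )
    mean_ab = table.data.mean(axis=0)
    for node in g.nodes:
        if node not in taxonomy:
            raise ValidationError(f"taxonomy missing for network OTU {node!r}")
        entry = taxonomy[node]
        g.nodes[node]["domain"] = entry.domain
        g.nodes[node]["phylum"] = entry.phylum
        g.nodes[node]["mean_abundance"] = float(mean_ab.get(node, np.nan))
    return g


def detect_modules(net: nx.Graph, resolution: float = 1.0, seed: int = 0) -> nx.Graph:
    """Louvain modules on the unweighted graph; ids dense, largest first.

    Sets the ``module`` node attribute and records the modularity value on
    ``net.graph["modularity"]``. Deterministic for a fixed seed.
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("cannot detect modules on an empty graph")
    comms = nx_community.louvain_communities(
        net, weight=None, resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=lambda c: (-len(c), sorted(c)[0]))
    for mid, members in enumerate(comms):
        for node in members:
            net.nodes[node]["module"] = mid
    net.graph["modularity"] = nx_community.modularity(net, comms, weight=None)
    return net


def renormalize_by_domain(table: OtuTable, taxonomy: TaxonomyMap) -> OtuTable:
    """Rescale each domain's abundances to sum 0.5 per sample.

    Bacteria and archaea come from separate sequencing runs, so their raw
    relative abundances are not on a common scale. Renormalizing each domain
    within each sample makes cross-domain correlations compare within-domain
    relative profiles; the factor 0.5 (instead of 1 per domain) keeps every
    sample row summing to 1. Spearman correlations are unchanged relative to
    the sum-to-1-per-domain variant because the extra factor is constant.
    Samples where a domain is entirely absent keep zeros for that domain.
    """
    for otu in table.otu_ids:
        if otu not in taxonomy:
            raise ValidationError(f"taxonomy missing for OTU {otu!r}")
    df = table.data.copy().astype(float)
    domains = np.array([taxonomy[o].domain for o in table.otu_ids])
    vals = df.to_numpy()
    out = np.zeros_like(vals)
    n_dom = len(set(domains))
    for dom in set(domains):
        cols = domains == dom
        sums = vals[:, cols].sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = np.where(sums > 0, vals[:, cols] / sums / n_dom, 0.0)
        out[:, cols] = scaled
    return OtuTable(pd.DataFrame(out, index=df.index, columns=df.columns))


def build_cooccurrence_network(
    table: OtuTable,
    taxonomy: TaxonomyMap,
    metadata: SampleMetadata,
    scope: str = "both",
    config: RunConfig | None = None,
    renormalize_domains: bool = True,
) -> nx.Graph:
    """Full pipeline: scope slice → prevalence filter → correlations → network → modules.

    The prevalence filter operates within the scope's own sample set, so the
    spring network sees only spring samples, etc.
    """
    cfg = config or RunConfig()
    samples = metadata.samples_for_scope(scope)
    scoped = table.subset_samples(samples)
    if renormalize_domains:
        scoped = renormalize_by_domain(scoped, taxonomy)
    prevalent = filter_by_prevalence(scoped, cfg.prevalence)
    corr = spearman_correlations(prevalent)
    net = build_network(
        corr, taxonomy, prevalent,
        rho_threshold=cfg.rho_threshold,
        q_threshold=cfg.q_threshold,
        use_absolute=cfg.use_absolute,
        scope=scope,
    )
    if net.number_of_nodes():
        detect_modules(net, seed=cfg.seed)
    return net
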