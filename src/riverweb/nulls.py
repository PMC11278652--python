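"""Erdős–Rényi null models, the small-world coefficient and degree-distribution fits.

The null ensemble is G(n, m): uniform simple graphs with exactly the
observed node and edge counts. Per replicate we record the mean local
clustering coefficient (CC), the average shortest-path length over
connected pairs (APL), and Louvain modularity (MD); the ensemble means CCr,
APLr and MDr enter the small-world coefficient σ = (CC/CCr)/(APL/APLr).
Degree distributions of real networks are compared against the ensemble by
fitting a power law a·k^(−γ) and a Gaussian to the degree probabilities and
comparing adjusted R².
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from networkx.algorithms import community as nx_community
from scipy import optimize, sparse
from scipy.sparse import csgraph

from .errors import ConfigurationError, ValidationError

__all__ = [
    "NullSummary",
    "DegreeFit",
    "average_path_length",
    "sample_er_ensemble",
    "small_world_sigma",
    "degree_histogram",
    "fit_degree_distribution",
]


@dataclass(frozen=True)
class NullSummary:
    """Ensemble means/SDs of clustering, path length and modularity."""

    n_graphs: int
    cc_mean: float
    cc_sd: float
    apl_mean: float | None
    apl_sd: float | None
    md_mean: float | None
    md_sd: float | None


@dataclass(frozen=True)
class DegreeFit:
    model: str                      # "power_law" | "gaussian"
    params: dict
    adj_r_squared: float | None
    n_points: int
    converged: bool


def average_path_length(g: nx.Graph) -> float | None:
    """Mean shortest-path length over all connected node pairs (unweighted).

    Returns None when no connected pair exists (empty or edgeless graph).
    Computed by BFS on the sparse adjacency, so it stays fast at the
    ~1000-node scale of the null ensembles.
    """
    n = g.number_of_nodes()
    if n < 2 or g.number_of_edges() == 0:
        return None
    adj = nx.to_scipy_sparse_array(g, format="csr", dtype=np.int8)
    dist = csgraph.shortest_path(adj, method="D", unweighted=True, directed=False)
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    finite = np.isfinite(d)
    if not finite.any():
        return None
    return float(d[finite].mean())


def _graph_metrics(g: nx.Graph, metrics, seed: int):
    out = {}
    if "cc" in metrics:
        out["cc"] = nx.average_clustering(g) if g.number_of_edges() else 0.0
    if "apl" in metrics:
        out["apl"] = average_path_length(g)
    if "md" in metrics:
        if g.number_of_edges() == 0:
            out["md"] = None
        else:
            comms = nx_community.louvain_communities(g, weight=None, seed=seed)
            out["md"] = nx_community.modularity(g, comms, weight=None)
    return out


def sample_er_ensemble(
    n_nodes: int,
    n_edges: int,
    n_graphs: int = 1000,
    seed: int | None = None,
    metrics: tuple = ("cc", "apl", "md"),
) -> NullSummary:
    """G(n, m) ensemble summary: means and SDs of CC, APL and MD.

    Each replicate is a uniform simple graph with exactly ``n_edges`` edges.
    Nodes of degree < 2 contribute 0 to the mean local clustering. APL is
    averaged over connected pairs only and reported missing (None) when the
    graph has no edges. ``metrics`` can be restricted to skip the costlier
    statistics.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ConfigurationError(
            f"n_edges={n_edges} outside [0, {max_edges}] for n_nodes={n_nodes}"
        )
    if n_graphs < 1:
        raise ConfigurationError("n_graphs must be >= 1")
    rng = np.random.default_rng(seed)
    ccs, apls, mds = [], [], []
    for i in range(n_graphs):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=rep_seed)
        m = _graph_metrics(g, metrics, seed=rep_seed)
        if "cc" in m:
            ccs.append(m["cc"])
        if "apl" in m and m["apl"] is not None:
            apls.append(m["apl"])
        if "md" in m and m["md"] is not None:
            mds.append(m["md"])

    def _agg(xs):
        if not xs:
            return None, None
        arr = np.asarray(xs, dtype=float)
        return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0

    cc_mean, cc_sd = _agg(ccs) if "cc" in metrics else (float("nan"), float("nan"))
    apl_mean, apl_sd = _agg(apls)
    md_mean, md_sd = _agg(mds)
    return NullSummary(
        n_graphs=n_graphs,
        cc_mean=cc_mean if cc_mean is not None else 0.0,
        cc_sd=cc_sd if cc_sd is not None else 0.0,
        apl_mean=apl_mean, apl_sd=apl_sd,
        md_mean=md_mean, md_sd=md_sd,
    )


def small_world_sigma(cc: float, ccr: float, apl: float, aplr: float) -> float:
    """σ = (CC/CCr)/(APL/APLr); σ ≫ 1 marks small-world structure."""
    for name, v in (("cc", cc), ("ccr", ccr), ("apl", apl), ("aplr", aplr)):
        if not v > 0:
            raise ValidationError(f"{name} must be positive, got {v!r}")
    return (cc / ccr) / (apl / aplr)


def degree_histogram(net: nx.Graph) -> list[tuple[int, int, float]]:
    """(degree, frequency, probability) rows; zero-frequency degrees omitted."""
    if net.number_of_nodes() == 0:
        raise ValidationError("degree histogram of an empty graph")
    degs = np.array([d for _, d in net.degree()])
    ks, counts = np.unique(degs, return_counts=True)
    n = degs.size
    return [(int(k), int(c), c / n) for k, c in zip(ks, counts)]


def _power_law(k, a, gamma):
    return a * np.power(k, -gamma)


def _gaussian(k, amp, mu, s):
    return amp * np.exp(-((k - mu) ** 2) / (2.0 * s * s))


def fit_degree_distribution(hist, model: str) -> DegreeFit:
    """Nonlinear least squares of P(k) against a power law or a Gaussian.

    Both models are fitted on the raw probabilities (not log residuals) so
    their adjusted R² values are directly comparable. Power-law starting
    values come from log–log OLS (k = 0 rows are dropped for that model);
    Gaussian starting values from histogram moments. Non-convergence after a
    restart grid yields a flagged fit with missing R².
    """
    rows = [(k, p) for k, _, p in hist]
    if model == "power_law":
        rows = [(k, p) for k, p in rows if k > 0]
        min_pts, n_par = 4, 2
    elif model == "gaussian":
        min_pts, n_par = 5, 3
    else:
        raise ConfigurationError(f"unknown model {model!r}")
    k = np.array([r[0] for r in rows], dtype=float)
    p = np.array([r[1] for r in rows], dtype=float)
    if len(np.unique(k)) < min_pts:
        raise ValidationError(
            f"{model} fit needs >= {min_pts} distinct degrees, got {len(np.unique(k))}"
        )

    if model == "power_law":
        pos = p > 0
        slope, intercept = np.polyfit(np.log(k[pos]), np.log(p[pos]), 1)
        starts = [(float(np.exp(intercept)), float(-slope))]
        starts += [(s0 * f, g0) for (s0, g0) in starts for f in (0.1, 10.0)]
        func = _power_law
        names = ("a", "gamma")
    else:
        mu0 = float((k * p).sum() / p.sum())
        s0 = float(np.sqrt(((k - mu0) ** 2 * p).sum() / p.sum())) or 1.0
        amp0 = float(p.max())
        k_mode = float(k[int(np.argmax(p))])
        span = float(k.max() - k.min()) or 1.0
        starts = [
            (amp0, mu0, s0), (amp0, mu0, 2 * s0), (2 * amp0, mu0, s0 / 2),
            (amp0, k_mode, s0), (amp0, k_mode, span / 4), (amp0, k.min(), span / 2),
        ]
        func = _gaussian
        names = ("amplitude", "mu", "s")

    if model == "gaussian":
        span = float(k.max() - k.min()) or 1.0
        bounds = ([0.0, k.min() - span, 1e-9],
                  [np.inf, k.max() + span, 100.0 * span])
    else:
        bounds = ([0.0, -np.inf], [np.inf, np.inf])

    best = None
    for x0 in starts:
        x0 = tuple(np.clip(x0, bounds[0], bounds[1]))
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                popt, _ = optimize.curve_fit(
                    func, k, p, p0=x0, maxfev=20000, bounds=bounds
                )
        except (RuntimeError, ValueError):
            continue
        resid = p - func(k, *popt)
        ss_res = float((resid ** 2).sum())
        if best is None or ss_res < best[1]:
            best = (popt, ss_res)
    if best is None:
        return DegreeFit(model, {}, None, len(k), converged=False)
    popt, ss_res = best
    ss_tot = float(((p - p.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    n = len(k)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_par - 1)
    return DegreeFit(
        model, dict(zip(names, map(float, popt))), float(adj), n, converged=True
    )
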