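"""Distance decay, environmental-driver correlations, and db-RDA.

Geographic structure of the networks is probed three ways: Mantel tests
(Spearman variant, 999 permutations) between geodetic distance and
Bray–Curtis dissimilarity matrices; an OLS distance-decay curve of
Bray–Curtis similarity against distance; and distance-based redundancy
analysis (db-RDA, capscale-style) of the network-member community on
standardized environmental factors. Environmental drivers of modules and
topology are screened with a BH-adjusted Spearman correlation heatmap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .network import benjamini_hochberg
from .tables import OtuTable, SampleMetadata

logger = logging.getLogger("riverweb")

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "DbRdaResult",
    "geodetic_distance_matrix",
    "bray_curtis_matrix",
    "mantel_test",
    "distance_decay_fit",
    "module_total_abundance",
    "env_network_correlations",
    "significant_fraction",
    "db_rda",
]


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple
    values: np.ndarray          # square, symmetric, zero diagonal
    metric: str                 # "geodetic-km" | "bray-curtis"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if np.abs(np.diag(v)).max(initial=0) > 1e-12:
            raise ValidationError("distance matrix diagonal not zero")

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int


@dataclass(frozen=True)
class DbRdaResult:
    """Axis variance and per-factor marginal tests of a db-RDA.

    ``axis_pct``: percent of total (retained) inertia explained by the
    constrained axes. ``factors`` columns: r_squared, adj_r_squared, p.
    """

    axis_pct: np.ndarray
    factors: pd.DataFrame
    full_model_r_squared: float
    n_samples: int


def _haversine_km(lat1, lon1, lat2, lon2) -> float:
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1))))


def geodetic_distance_matrix(metadata: SampleMetadata) -> DistanceMatrix:
    """Pairwise great-circle (haversine) distances in km between samples."""
    df = metadata.data
    lat = df["latitude"].to_numpy(dtype=float)
    lon = df["longitude"].to_numpy(dtype=float)
    missing = df.index[np.isnan(lat) | np.isnan(lon)]
    if len(missing):
        raise ValidationError(f"missing coordinates for samples: {list(missing)}")
    n = len(df)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _haversine_km(lat[i], lon[i], lat[j], lon[j])
            out[i, j] = out[j, i] = d
    return DistanceMatrix(tuple(df.index), out, "geodetic-km")


def bray_curtis_matrix(
    matrix: pd.DataFrame, scale_features: bool = False
) -> DistanceMatrix:
    """Bray–Curtis dissimilarities BC(a,b) = Σ|a−b| / Σ(a+b) between rows.

    With ``scale_features`` (used for topology-feature matrices that contain
    negatives such as assortativity), each column is min–max scaled to
    [0, 1] first and constant columns are dropped. A pair of all-zero rows
    gets distance 0 with a warning.
    """
    df = matrix.astype(float)
    if scale_features:
        rng_ = df.max() - df.min()
        keep = rng_ > 0
        df = (df.loc[:, keep] - df.loc[:, keep].min()) / rng_[keep]
    vals = df.to_numpy()
    if np.nanmin(vals, initial=0) < 0:
        raise ValidationError(
            "Bray–Curtis requires nonnegative values; use scale_features=True"
        )
    with np.errstate(invalid="ignore"):
        condensed = pdist(vals, metric="braycurtis")
    if np.isnan(condensed).any():
        warnings.warn("all-zero sample pair(s): Bray–Curtis distance set to 0")
        condensed = np.nan_to_num(condensed, nan=0.0)
    return DistanceMatrix(tuple(df.index), squareform(condensed), "bray-curtis")


def _check_aligned(da: DistanceMatrix, db_: DistanceMatrix) -> None:
    if da.ids != db_.ids:
        raise ValidationError("distance matrices have different sample orderings")


def mantel_test(
    dA: DistanceMatrix,
    dB: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Spearman Mantel test, one-sided (positive association).

    r is the Spearman correlation of the upper-triangle entries; the null
    is generated by simultaneous row/column permutation of the second
    matrix; p = (#{r_perm >= r_obs} + 1)/(n_permutations + 1).
    """
    _check_aligned(dA, dB)
    n = len(dA.ids)
    if n < 5:
        raise ValidationError("Mantel test needs at least 5 samples")
    iu = np.triu_indices(n, k=1)
    # Ranks of the condensed entries are invariant under relabeling, so the
    # rank matrices are built once and only permuted.
    ra = np.zeros((n, n))
    ra[iu] = stats.rankdata(dA.values[iu])
    ra = ra + ra.T
    rb = np.zeros((n, n))
    rb[iu] = stats.rankdata(dB.values[iu])
    rb = rb + rb.T

    def _corr(a_vec, b_vec):
        a_c = a_vec - a_vec.mean()
        b_c = b_vec - b_vec.mean()
        denom = np.sqrt((a_c ** 2).sum() * (b_c ** 2).sum())
        if denom == 0:
            raise ValidationError("constant distance matrix in Mantel test")
        return float((a_c * b_c).sum() / denom)

    a_vec = ra[iu]
    r_obs = _corr(a_vec, rb[iu])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        hits += _corr(a_vec, rb[np.ix_(perm, perm)][iu]) >= r_obs
    p = (hits + 1) / (n_permutations + 1)
    return MantelResult(r=r_obs, p=float(p), n_permutations=n_permutations)


def distance_decay_fit(
    geo: DistanceMatrix,
    community: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float, MantelResult]:
    """OLS of Bray–Curtis similarity (1 − dissimilarity) on geodetic distance.

    Returns (slope per km, intercept, Mantel result). A negative slope is
    the distance-decay signature.
    """
    _check_aligned(geo, community)
    x = geo.condensed
    if len(np.unique(x)) < 3:
        raise ValidationError("need >= 3 distinct pairwise distances")
    y = 1.0 - community.condensed
    slope, intercept = np.polyfit(x, y, 1)
    if np.ptp(y) == 0:
        # constant similarity: slope is exactly 0 and no rank association
        # is definable, so no Mantel result is attached
        return 0.0, float(intercept), None
    mantel = mantel_test(geo, community, n_permutations=n_permutations, seed=seed)
    return float(slope), float(intercept), mantel


def module_total_abundance(net: nx.Graph, table: OtuTable) -> pd.DataFrame:
    """Per-sample total relative abundance of each detected module's members."""
    modules: dict[int, list[str]] = {}
    for node, data in net.nodes(data=True):
        if "module" not in data:
            raise ValidationError("network has no module assignments")
        modules.setdefault(int(data["module"]), []).append(node)
    cols = {}
    for mid in sorted(modules):
        members = [o for o in modules[mid] if o in table.data.columns]
        cols[f"module_{mid}"] = table.data[members].sum(axis=1)
    return pd.DataFrame(cols, index=table.data.index)


def env_network_correlations(
    env: pd.DataFrame,
    responses: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman rho/p/q for every env factor × response (module or feature).

    Pairwise-complete on missing values; a constant env factor yields
    missing rho for its row. q is BH-adjusted over every computed cell of
    the table.
    """
    env = env.astype(float)
    responses = responses.astype(float).reindex(env.index)
    recs = []
    for factor in env.columns:
        x_all = env[factor]
        for resp in responses.columns:
            y_all = responses[resp]
            mask = x_all.notna() & y_all.notna()
            x, y = x_all[mask].to_numpy(), y_all[mask].to_numpy()
            if len(x) < 5 or np.all(x == x[0]) or np.all(y == y[0]):
                recs.append(dict(env=factor, response=resp,
                                 rho=np.nan, p=np.nan, n=int(len(x))))
                continue
            rho, p = stats.spearmanr(x, y)
            recs.append(dict(env=factor, response=resp,
                             rho=float(rho), p=float(p), n=int(len(x))))
    out = pd.DataFrame.from_records(recs)
    out["q"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = benjamini_hochberg(out.loc[ok, "p"].to_numpy())
    return out


def significant_fraction(corr_table: pd.DataFrame, alpha: float = 0.05,
                         use_adjusted: bool = True) -> float:
    """Fraction of computed heatmap cells significant at ``alpha``."""
    col = "q" if use_adjusted else "p"
    vals = corr_table[col].dropna()
    if vals.empty:
        raise ValidationError("no computed cells in correlation table")
    return float((vals < alpha).mean())


def _pcoa(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classical PCoA; returns (coordinates, positive eigenvalues)."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-8 * abs(evals[0])) if len(evals) else 0
    keep = evals > tol
    return evecs[:, keep] * np.sqrt(evals[keep]), evals[keep]


def _constrained_ss(y: np.ndarray, x: np.ndarray) -> float:
    """Sum of squares of Y explained by the column space of X (with intercept)."""
    xd = np.column_stack([np.ones(len(x)), x])
    beta, *_ = np.linalg.lstsq(xd, y, rcond=None)
    fitted = xd @ beta
    fitted -= fitted.mean(axis=0)
    return float((fitted ** 2).sum())


def db_rda(
    community: OtuTable,
    env: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | None = None,
) -> DbRdaResult:
    """Distance-based RDA of the community on standardized env factors.

    Bray–Curtis dissimilarities are decomposed by principal coordinates
    (negative-eigenvalue axes dropped); the coordinates are regressed on
    the z-scored factors. Axis percentages are constrained eigenvalue
    fractions of total retained inertia. Per-factor marginal tests refit a
    single-constraint model; the permutation p and the permutation-adjusted
    R² (1 − (1−R²)/(1−mean R²_perm)) are reported. Samples with any missing
    factor are dropped listwise.
    """
    env = env.astype(float).reindex(community.data.index)
    keep = env.notna().all(axis=1)
    if (~keep).any():
        logger.info("db_rda: dropping %d sample(s) with missing env", (~keep).sum())
    env = env.loc[keep]
    comm = community.data.loc[keep]
    n, k = env.shape
    if k < 2:
        raise ValidationError("db-RDA needs >= 2 env factors")
    if n <= k + 2:
        raise ValidationError("db-RDA needs n samples > n factors + 2")
    sd = env.std(ddof=1)
    const = list(sd.index[sd == 0])
    if const:
        raise ValidationError(f"constant env factor(s): {const}")
    x = ((env - env.mean()) / sd).to_numpy()
    cond = np.linalg.cond(np.column_stack([np.ones(n), x]))
    if cond > 1e8:
        raise ValidationError(
            f"collinear env factor set (condition number {cond:.3g}): "
            f"{list(env.columns)}"
        )
    d = squareform(pdist(comm.to_numpy(), metric="braycurtis"))
    y, evals = _pcoa(d)
    y = y - y.mean(axis=0)
    total_ss = float((y ** 2).sum())

    # full model: constrained axes from SVD of fitted coordinates
    xd = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(xd, y, rcond=None)
    fitted = xd @ beta
    fitted -= fitted.mean(axis=0)
    svals = np.linalg.svd(fitted, compute_uv=False)
    axis_ss = svals ** 2
    axis_ss = axis_ss[axis_ss > 1e-12 * total_ss]
    axis_pct = 100.0 * axis_ss / total_ss
    full_r2 = float((fitted ** 2).sum() / total_ss)

    rng = np.random.default_rng(seed)
    recs = []
    for i, factor in enumerate(env.columns):
        xi = x[:, [i]]
        r2 = _constrained_ss(y, xi) / total_ss
        perm_r2 = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = rng.permutation(n)
            perm_r2[b] = _constrained_ss(y, xi[perm]) / total_ss
        p = (np.sum(perm_r2 >= r2) + 1) / (n_permutations + 1)
        adj = 1.0 - (1.0 - r2) / (1.0 - perm_r2.mean())
        recs.append(dict(factor=factor, r_squared=float(r2),
                         adj_r_squared=float(adj), p=float(p)))
    factors = pd.DataFrame.from_records(recs).set_index("factor")
    return DbRdaResult(
        axis_pct=axis_pct, factors=factors,
        full_model_r_squared=full_r2, n_samples=n,
    )
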