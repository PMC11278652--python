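"""Tabular and graph I/O with explicit, bit-stable dialects.

All tables are TSV (tab-separated, UTF-8, '.' decimal); networks are GraphML
so they open directly in Gephi; run configuration round-trips through YAML.
Readers are total: malformed input raises a typed error with row/column
context, never a silently truncated structure.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

DOMAINS = ("Bacteria", "Archaea")
SEASONS = ("spring", "autumn")
LANDFORMS = ("plateau", "mountain/hill", "basin", "plain")
REGIONS = ("source", "non-source")

#: Environmental factor columns recognised in sample metadata, in report order.
ENV_FACTORS = (
    "WT", "pH", "COD_Mn", "NH4_N", "NO3_N", "TN", "TP",
    "Ca", "Fe", "Al", "Ni", "Cd",
)

_METADATA_REQUIRED = (
    "site_no", "season", "latitude", "longitude", "elevation", "landform", "region",
)


@dataclass(frozen=True)
class OtuTable:
    """Samples × OTUs relative-abundance matrix.

    ``data`` has sample ids on the index and OTU ids on the columns; values
    are dimensionless fractions in [0, 1] and each sample row sums to at
    most 1 (closure is enforced upstream, not here).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise FormatError(f"duplicate OTU id {dup!r}")
        vals = df.to_numpy(dtype=float)
        if vals.size and np.nanmin(vals) < 0:
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {df.index[i]!r}, OTU {df.columns[j]!r}"
            )
        if vals.size:
            sums = np.nansum(vals, axis=1)
            if sums.max() > 1 + 1e-6:
                bad = df.index[int(np.argmax(sums))]
                raise ValidationError(
                    f"sample {bad!r} abundances sum to {sums.max():.6g} > 1"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return OtuTable(self.data.loc[list(sample_ids)])


@dataclass(frozen=True)
class TaxonomyEntry:
    domain: str
    phylum: str
    lineage: Mapping[str, str] = field(default_factory=dict)


class TaxonomyMap(dict):
    """otu_id → :class:`TaxonomyEntry`; domains restricted to Bacteria/Archaea."""

    def __setitem__(self, otu_id: str, entry: TaxonomyEntry) -> None:
        if entry.domain not in DOMAINS:
            raise ValidationError(
                f"OTU {otu_id!r}: domain {entry.domain!r} not in {DOMAINS}"
            )
        if not entry.phylum:
            raise ValidationError(f"OTU {otu_id!r}: empty phylum")
        super().__setitem__(otu_id, entry)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample site, season, landform and environmental measurements.

    ``data`` is indexed by sample id with the required descriptive columns
    plus any subset of :data:`ENV_FACTORS`; missing environmental values are
    NaN (flagged missing, never silently zero).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in _METADATA_REQUIRED:
            if col not in df.columns:
                raise FormatError(f"metadata missing required column {col!r}")
        bad_season = set(df["season"]) - set(SEASONS)
        if bad_season:
            raise ValidationError(f"unknown season value(s): {sorted(bad_season)}")
        bad_lf = set(df["landform"]) - set(LANDFORMS)
        if bad_lf:
            raise ValidationError(f"unknown landform value(s): {sorted(bad_lf)}")
        bad_rg = set(df["region"]) - set(REGIONS)
        if bad_rg:
            raise ValidationError(f"unknown region value(s): {sorted(bad_rg)}")
        lat = df["latitude"].to_numpy(dtype=float)
        lon = df["longitude"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(lat), initial=0) > 90:
                raise ValidationError("latitude outside [-90, 90]")
            if np.nanmax(np.abs(lon), initial=0) > 180:
                raise ValidationError("longitude outside [-180, 180]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def env_factors(self) -> list[str]:
        return [c for c in self.data.columns if c in ENV_FACTORS]

    @property
    def env(self) -> pd.DataFrame:
        return self.data[self.env_factors].astype(float)

    def samples_for_scope(self, scope: str) -> list[str]:
        """Sample ids for a network scope: 'spring', 'autumn' or 'both'."""
        if scope == "both":
            return self.sample_ids
        if scope not in SEASONS:
            raise ValidationError(f"unknown scope {scope!r}")
        mask = self.data["season"] == scope
        return list(self.data.index[mask])


@dataclass
class RunConfig:
    """Analysis thresholds; documented defaults are the study's values."""

    prevalence: float = 0.30
    rho_threshold: float = 0.6
    q_threshold: float = 0.01
    use_absolute: bool = False
    n_null_graphs: int = 1000
    n_permutations: int = 999
    degree_cutoff: float = 100.0
    betweenness_cutoff: float = 5000.0
    incidence_o_cutoff: float = 0.5
    incidence_ratio_cutoff: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prevalence", "rho_threshold", "q_threshold", "n_null_graphs",
                     "n_permutations", "degree_cutoff", "betweenness_cutoff"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"RunConfig.{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# TSV readers / writers


def write_otu_table(table: OtuTable, path) -> None:
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_otu_table(path) -> OtuTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty data section")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric abundance value ({exc})") from exc
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return OtuTable(df)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    rows = [
        {"otu_id": otu, "domain": e.domain, "phylum": e.phylum, **dict(e.lineage)}
        for otu, e in tax.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("otu_id", "domain", "phylum"):
        if col not in df.columns:
            raise FormatError(f"{path}: taxonomy missing column {col!r}")
    extra = [c for c in df.columns if c not in ("otu_id", "domain", "phylum")]
    tax = TaxonomyMap()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        otu = rec["otu_id"]
        if otu in tax:
            raise FormatError(f"{path}:{i}: duplicate OTU id {otu!r}")
        try:
            tax[otu] = TaxonomyEntry(
                domain=rec["domain"],
                phylum=rec["phylum"] if isinstance(rec["phylum"], str) else "",
                lineage={c: rec[c] for c in extra if isinstance(rec[c], str)},
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{i}: {exc}") from exc
    return tax


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if "season" in df.columns:
        df["season"] = df["season"].astype(str).str.strip().str.lower()
    if "landform" in df.columns:
        df["landform"] = df["landform"].astype(str).str.strip().str.lower()
    if "region" in df.columns:
        df["region"] = df["region"].astype(str).str.strip().str.lower()
    try:
        return SampleMetadata(df)
    except (FormatError, ValidationError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# GraphML


def write_network(net: nx.Graph, path) -> None:
    """Write a co-occurrence network as GraphML (Gephi-compatible).

    Edge ``rho`` is stored as a double (full repr precision, well beyond 6
    significant digits); node taxonomy/abundance/module and the graph-level
    scope/modularity attributes round-trip.
    """
    nx.write_graphml(net, path)


def read_network(path) -> nx.Graph:
    g = nx.read_graphml(path)
    return nx.Graph(g)


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))
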