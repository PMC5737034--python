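"""Core containers and shared operations for OTU-table analyses.

The central object is :class:`OTUTable`, an integer read-count matrix of
samples by OTUs.  Everything downstream (rarity partitioning, diversity,
niche breadth, ordination, neutral-model fitting) consumes either this
table, its relative-abundance counterpart, or a :class:`DistanceMatrix`
derived from it.  Readers and writers speak plain TSV so tables round-trip
through files bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
#: aggregation levels accepted by :func:`aggregate_by_rank`, finest first
AGG_RANKS = ("otu", "genus", "family", "order", "class", "phylum")
UNCLASSIFIED = "unclassified"

#: environmental covariates carried by :class:`SampleMetadata`; pH is the
#: only one exempt from the log(x+1) transform (it is already log-scaled).
ENV_VARIABLES = ("pH", "salinity", "TC", "TN", "TS", "TP", "NH4-N", "NOx-N")

EARTH_RADIUS_KM = 6371.0


class TableError(ValueError):
    """Raised for malformed tables or invalid table operations."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class OTUTable:
    """Read counts, samples as rows and OTUs as columns.

    ``data`` is an integer DataFrame indexed by sample id with OTU ids as
    columns.  The table is *rarefied* when every row sums to the same depth.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise TableError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise TableError(f"duplicate OTU ids: {dups}")
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise TableError("table needs at least one sample and one OTU")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            rounded = np.rint(values)
            off = np.abs(values - rounded) > 1e-6
            if off.any():
                i, j = np.argwhere(off)[0]
                raise TableError(
                    f"non-integer count at sample {df.index[i]!r}, "
                    f"OTU {df.columns[j]!r}: {values[i, j]}"
                )
            df = pd.DataFrame(rounded.astype(np.int64), index=df.index, columns=df.columns)
            self.data = df
        if (self.data.to_numpy() < 0).any():
            raise TableError("negative counts are not allowed")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    @property
    def total_reads(self) -> int:
        return int(self.data.to_numpy().sum())

    @property
    def rarefied(self) -> bool:
        sums = self.sample_sums.to_numpy()
        return bool((sums == sums[0]).all())

    def drop_empty_otus(self) -> "OTUTable":
        keep = self.data.sum(axis=0) > 0
        return OTUTable(self.data.loc[:, keep])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OTUTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class RelativeAbundanceTable:
    """Row-normalized proportions on the same axes as an :class:`OTUTable`."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.data.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise TableError("relative-abundance rows must sum to 1")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class TaxonomyTable:
    """Lineages of up to seven ranks per OTU; unresolved ranks are explicit
    ``"unclassified"`` placeholders."""

    data: pd.DataFrame  # index otu_id, columns RANKS

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.data.columns]
        if missing:
            raise TableError(f"taxonomy missing ranks: {missing}")
        self.data = self.data.loc[:, list(RANKS)].fillna(UNCLASSIFIED).astype(str)

    def lineage(self, otu_id) -> tuple:
        return tuple(self.data.loc[otu_id])

    def for_table(self, table: OTUTable) -> "TaxonomyTable":
        """Lineages aligned to ``table``; OTUs without a row become
        all-unclassified."""
        aligned = self.data.reindex(table.otu_ids).fillna(UNCLASSIFIED)
        return TaxonomyTable(aligned)


@dataclass
class SampleMetadata:
    """Per-sample habitat (vegetation zone), season, coordinates, and
    environmental covariates."""

    data: pd.DataFrame  # index sample_id

    def __post_init__(self) -> None:
        for col in ("habitat", "season"):
            if col not in self.data.columns:
                raise TableError(f"metadata missing required column {col!r}")
        if self.data.index.has_duplicates:
            raise TableError("duplicate sample ids in metadata")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def habitat(self) -> pd.Series:
        return self.data["habitat"]

    @property
    def season(self) -> pd.Series:
        return self.data["season"]

    @property
    def env_columns(self) -> list:
        reserved = {"habitat", "season", "latitude", "longitude"}
        return [
            c
            for c in self.data.columns
            if c not in reserved and pd.api.types.is_numeric_dtype(self.data[c])
        ]

    def env(self, variables: Sequence[str] | None = None) -> pd.DataFrame:
        cols = list(variables) if variables is not None else self.env_columns
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise TableError(f"metadata missing variables: {missing}")
        return self.data[cols].astype(float)

    def check_covers(self, table: OTUTable) -> None:
        missing = [s for s in table.sample_ids if s not in self.data.index]
        if missing:
            raise TableError(f"samples without metadata: {missing}")

    def aligned_to(self, table: OTUTable) -> "SampleMetadata":
        self.check_covers(table)
        return SampleMetadata(self.data.loc[table.sample_ids])


@dataclass
class DistanceMatrix:
    """Square symmetric distances with a metric label."""

    ids: list
    values: np.ndarray
    metric: str = "bray_curtis"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise TableError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise TableError("distance matrix is not symmetric")
        if (v < 0).any():
            raise TableError("distances must be non-negative")
        np.fill_diagonal(v, 0.0)
        self.values = v
        self.ids = list(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Lower/upper-triangle entries in scipy's condensed order."""
        return squareform(self.values, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def between(self, a, b) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


# ---------------------------------------------------------------------------
# TSV readers / writers


def read_otu_table(path, orientation: str = "otus_as_rows") -> OTUTable:
    """Read a TSV count table.

    ``orientation`` declares whether the file has OTUs as rows (the common
    ``#OTU_ID`` dialect, the writer's output) or samples as rows.
    """
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise TableError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        sample, col = next(
            (i, c) for c in df.columns for i in df.index if pd.isna(df.at[i, c])
        )
        raise TableError(f"missing value at row {sample!r}, column {col!r} in {path}")
    if orientation == "otus_as_rows":
        df = df.T
    df.index.name = None
    df.columns.name = None
    return OTUTable(df)


def write_otu_table(table: OTUTable, path) -> None:
    """Write OTUs-as-rows TSV with a ``#OTU_ID`` header column."""
    out = table.data.T
    out.index.name = "#OTU_ID"
    out.to_csv(path, sep="\t")


def _parse_lineage(text: str) -> list:
    parts = [p.strip() for p in str(text).split(";")]
    clean = []
    for p in parts:
        if "__" in p:  # Greengenes-style k__Bacteria prefixes
            p = p.split("__", 1)[1]
        clean.append(p if p else UNCLASSIFIED)
    clean = clean[: len(RANKS)]
    clean += [UNCLASSIFIED] * (len(RANKS) - len(clean))
    return clean


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", header=None, names=["otu_id", "lineage"], dtype=str)
    if df["otu_id"].duplicated().any():
        dup = df.loc[df["otu_id"].duplicated(), "otu_id"].iloc[0]
        raise TableError(f"duplicate OTU id in taxonomy: {dup!r}")
    rows = [_parse_lineage(t) for t in df["lineage"]]
    out = pd.DataFrame(rows, index=df["otu_id"].tolist(), columns=list(RANKS))
    return TaxonomyTable(out)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    lineages = tax.data.apply(lambda row: ";".join(row), axis=1)
    lineages.to_csv(path, sep="\t", header=False)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    out = meta.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_distance_matrix(path, metric: str = "unknown") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(float), metric)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.to_dataframe().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# operations


def rarefy(table: OTUTable, depth: int, seed: int) -> OTUTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Each sample's reads form a multiset; ``depth`` reads are drawn uniformly
    without replacement (multivariate hypergeometric), so expected counts are
    proportional to the input composition.  OTUs reduced to zero everywhere
    are retained.  The same seed reproduces the same table.
    """
    depth = int(depth)
    if depth < 1:
        raise TableError("depth must be >= 1")
    sums = table.sample_sums
    short = sums[sums < depth]
    if len(short):
        raise TableError(
            "samples with fewer reads than depth "
            f"{depth}: {dict(short.astype(int))}"
        )
    rng = np.random.default_rng(seed)
    rows = [
        rng.multivariate_hypergeometric(row, depth)
        for row in table.counts.astype(np.int64)
    ]
    out = pd.DataFrame(
        np.asarray(rows, dtype=np.int64), index=table.data.index, columns=table.data.columns
    )
    return OTUTable(out)


def to_relative(table: OTUTable) -> RelativeAbundanceTable:
    sums = table.sample_sums.to_numpy()
    if (sums == 0).any():
        empty = [s for s, t in zip(table.sample_ids, sums) if t == 0]
        raise TableError(f"all-zero samples cannot be normalized: {empty}")
    rel = table.data.div(table.sample_sums, axis=0)
    return RelativeAbundanceTable(rel)


def _group_key(lineage: Sequence[str], depth: int) -> str:
    """Deepest-resolved-prefix key for aggregation at lineage depth ``depth``.

    A trailing run of unclassified ranks collapses onto its deepest resolved
    ancestor, so unrelated unclassified taxa in different clades never merge.
    """
    prefix = list(lineage[:depth])
    if prefix and prefix[-1] == UNCLASSIFIED:
        while prefix and prefix[-1] == UNCLASSIFIED:
            prefix.pop()
        prefix.append(UNCLASSIFIED)
    return ";".join(prefix) if prefix else UNCLASSIFIED


def aggregate_by_rank(table: OTUTable, taxonomy: TaxonomyTable, rank: str) -> OTUTable:
    """Sum counts of OTUs sharing a lineage prefix down to ``rank``.

    ``rank="otu"`` is the identity.  Per-sample totals are conserved exactly.
    """
    if rank not in AGG_RANKS:
        raise TableError(f"unknown rank {rank!r}; expected one of {AGG_RANKS}")
    if rank == "otu":
        return OTUTable(table.data.copy())
    depth = len(RANKS) - AGG_RANKS.index(rank)  # genus -> 6 ... phylum -> 2
    tax = taxonomy.for_table(table)
    keys = [_group_key(tuple(row), depth) for row in tax.data.to_numpy()]
    grouped = table.data.T.groupby(pd.Index(keys, name=None), sort=True).sum().T
    grouped.columns.name = None
    return OTUTable(grouped)


def bray_curtis(
    table: OTUTable | RelativeAbundanceTable, as_similarity: bool = False
) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    ``d(x, y) = 1 - 2 sum_k min(x_k, y_k) / (sum x + sum y)``; on
    relative-abundance rows this equals ``0.5 * sum |x - y|``.
    """
    x = table.data.to_numpy(float)
    if x.shape[0] < 2:
        raise TableError("need at least 2 samples for a distance matrix")
    zero_rows = np.flatnonzero(x.sum(axis=1) == 0)
    if len(zero_rows) >= 2:
        bad = [table.sample_ids[i] for i in zero_rows]
        raise TableError(f"Bray-Curtis undefined between all-zero samples: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    if as_similarity:
        d = 1.0 - d
    return DistanceMatrix(table.sample_ids, d, "bray_curtis")


def env_transform(env: pd.DataFrame, log_exempt: Iterable[str] = ("pH",)) -> pd.DataFrame:
    """log(x+1)-transform covariates (pH exempt), then standardize each to
    zero mean / unit variance (population SD; constant columns stay 0)."""
    exempt = set(log_exempt)
    out = env.astype(float).copy()
    for col in out.columns:
        if col not in exempt:
            if (out[col] <= -1).any():
                raise TableError(f"variable {col!r} has values <= -1; log(x+1) undefined")
            out[col] = np.log1p(out[col])
    centered = out - out.mean()
    sd = out.std(ddof=0)
    for col in out.columns:
        centered[col] = centered[col] / sd[col] if sd[col] > 0 else 0.0
    return centered


def env_distance(
    meta: SampleMetadata, variables: Sequence[str] | None = None
) -> DistanceMatrix:
    """Euclidean distance on transformed, standardized covariates."""
    env = meta.env(variables)
    na = env.isna()
    if na.any().any():
        bad = [(i, c) for c in env.columns for i in env.index if na.at[i, c]]
        raise TableError(f"missing environmental values: {bad}")
    z = env_transform(env)
    d = squareform(pdist(z.to_numpy(), metric="euclidean"))
    return DistanceMatrix(meta.sample_ids, d, "euclidean")


def geographic_distance(meta: SampleMetadata) -> DistanceMatrix:
    """Great-circle (haversine) distance in km, sphere radius 6,371 km."""
    for col in ("latitude", "longitude"):
        if col not in meta.data.columns:
            raise TableError(f"metadata missing {col!r}")
    lat = meta.data["latitude"].to_numpy(float)
    lon = meta.data["longitude"].to_numpy(float)
    if (np.abs(lat) > 90).any() or (np.abs(lon) > 180).any():
        raise TableError("coordinates outside valid ranges")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    return DistanceMatrix(meta.sample_ids, d, "geographic")
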