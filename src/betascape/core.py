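"""Community tables, sample metadata, normalization, diversity and distances.

The central container is :class:`CommunityTable`, a validated samples ×
features abundance matrix (ASV counts, KEGG-ortholog profiles, or
taxon-family counts).  Everything downstream — dispersion testing, spatial
statistics, assembly models, networks, trait profiling — consumes either a
``CommunityTable`` or a Bray–Curtis :class:`skbio.DistanceMatrix` derived
from one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)

FEATURE_KINDS = frozenset({"asv", "gene", "taxon_family"})
NORMALIZATIONS = frozenset({"raw", "rarefied", "relative", "cpm"})

EARTH_RADIUS_KM = 6371.0

#: required columns of a metadata file, in canonical order
METADATA_REQUIRED = (
    "sample_id",
    "site_id",
    "land_use",
    "replicate",
    "latitude",
    "longitude",
)


@dataclass
class CommunityTable:
    """Samples × features abundance matrix with provenance tags.

    Parameters
    ----------
    data :
        DataFrame indexed by sample id, columns are feature ids.  Counts
        must be non-negative; real values are accepted (normalized gene
        tables), integers are expected for raw ASV/taxon tables.
    feature_kind :
        One of ``asv``, ``gene``, ``taxon_family``.
    normalization :
        One of ``raw``, ``rarefied``, ``relative``, ``cpm``.
    """

    data: pd.DataFrame
    feature_kind: str = "asv"
    normalization: str = "raw"

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicated sample ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicated feature ids: {dupes}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("abundance table must be numeric")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )

    # -- conveniences -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def relative(self) -> "CommunityTable":
        """Row-normalize to relative abundances summing to 1."""
        sums = self.data.sum(axis=1)
        _check_positive_rows(sums)
        return CommunityTable(
            self.data.div(sums, axis=0), self.feature_kind, "relative"
        )


@dataclass
class SampleMetadata:
    """Per-sample design and environmental covariates.

    One row per sample; ``(site_id, land_use, replicate)`` must be unique.
    Any numeric column beyond the required design columns is treated as an
    environmental covariate (pH, TC, TN, ... optionally AGS).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
            self.data = df
        missing = [c for c in METADATA_REQUIRED[1:] if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if df.index.has_duplicates:
            raise ValueError("duplicated sample ids in metadata")
        keys = df[["site_id", "land_use", "replicate"]]
        if keys.duplicated().any():
            raise ValueError("(site_id, land_use, replicate) not unique")
        bad_lu = set(df["land_use"]) - {"AS", "NS"}
        if bad_lu:
            raise ValueError(f"unknown land_use labels: {sorted(bad_lu)}")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def env_columns(self) -> list:
        design = set(METADATA_REQUIRED)
        return [
            c
            for c in self.data.columns
            if c not in design and pd.api.types.is_numeric_dtype(self.data[c])
        ]

    def env(self) -> pd.DataFrame:
        """Environmental covariates only (numeric, non-design columns)."""
        return self.data[self.env_columns]

    def aligned_to(self, table: CommunityTable) -> "SampleMetadata":
        """Reindex to the table's samples; every sample must be present."""
        missing = [s for s in table.sample_ids if s not in self.data.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing[:5]}")
        return SampleMetadata(self.data.loc[table.sample_ids].copy())


@dataclass
class AlphaDiversity:
    """Per-sample richness (observed features) and Shannon index."""

    data: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_table(path, kind: str = "asv", features_as_rows: bool = True,
               normalization: str = "raw") -> CommunityTable:
    """Read a TSV feature table.

    The conventional layout has features as rows (first column the feature
    id, commonly headed ``#FeatureID``) and samples as columns; pass
    ``features_as_rows=False`` for a samples × features layout.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str).rename(None)
    if features_as_rows:
        df = df.T
    return CommunityTable(df, feature_kind=kind, normalization=normalization)


def write_table(table: CommunityTable, path, features_as_rows: bool = True) -> None:
    df = table.data.T if features_as_rows else table.data
    label = "#FeatureID" if features_as_rows else "sample_id"
    df.to_csv(path, sep="\t", index_label=label)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("metadata must contain a sample_id column")
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.data.to_csv(path, sep="\t", index_label="sample_id")


def read_biom_table(path, kind: str = "asv") -> CommunityTable:
    """Optional BIOM-format reader (requires the ``biom-format`` package)."""
    try:
        import biom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading BIOM files requires the biom-format package") from exc
    bt = biom.load_table(path)
    df = bt.to_dataframe(dense=True).T  # biom stores features x samples
    return CommunityTable(df, feature_kind=kind)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """Write a labeled square TSV."""
    dm.to_data_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _check_positive_rows(sums: pd.Series) -> None:
    zero = sums.index[sums <= 0].tolist()
    if zero:
        raise ValueError(f"zero-sum sample rows: {zero}")


def rarefy(table: CommunityTable, depth: int, seed: int | None = None) -> CommunityTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a logged
    warning.  Exact multivariate-hypergeometric subsampling, reproducible
    under a fixed seed.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    counts = table.counts
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("rarefaction requires integer counts")
    counts = np.round(counts).astype(np.int64)
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, dropped[:10],
        )
    rng = np.random.default_rng(seed)
    out = np.empty((int(keep.sum()), counts.shape[1]), dtype=np.int64)
    for i, row in enumerate(counts[keep]):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    df = pd.DataFrame(out, index=kept_ids, columns=table.feature_ids)
    return CommunityTable(df, table.feature_kind, "rarefied")


def cpm_normalize(table: CommunityTable) -> CommunityTable:
    """Counts-per-million normalization: each row rescaled to sum to 1e6."""
    sums = table.data.sum(axis=1)
    _check_positive_rows(sums)
    df = table.data.div(sums, axis=0) * 1e6
    return CommunityTable(df, table.feature_kind, "cpm")


# ---------------------------------------------------------------------------
# Distances and diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity, D_ij = Σ|x_i − x_j| / Σ(x_i + x_j)."""
    counts = table.counts.astype(float)
    _check_positive_rows(pd.Series(counts.sum(axis=1), index=table.sample_ids))
    condensed = pdist(counts, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(s) for s in table.sample_ids])


def geo_distance(metadata: SampleMetadata, planar: bool = False) -> DistanceMatrix:
    """Pairwise geographic distance between samples.

    Default is great-circle (haversine) distance in km on a sphere of
    radius 6371 km, so distance–decay slopes carry per-km units.  With
    ``planar=True`` the distance is the literal Euclidean distance in
    decimal degrees.
    """
    lat = metadata.data["latitude"].to_numpy(dtype=float)
    lon = metadata.data["longitude"].to_numpy(dtype=float)
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180):
        raise ValueError("longitude outside [-180, 180]")
    ids = [str(s) for s in metadata.sample_ids]
    if planar:
        pts = np.column_stack([lat, lon])
        return DistanceMatrix(squareform(pdist(pts)), ids=ids)
    return DistanceMatrix(haversine_matrix(lat, lon), ids=ids)


def haversine_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix in km (Earth radius 6371 km)."""
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (
        np.sin(dphi / 2.0) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    )
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    return d


def alpha_diversity(table: CommunityTable, base: float = math.e) -> AlphaDiversity:
    """Richness (nonzero features) and Shannon index per sample.

    Shannon H = −Σ p_k log p_k over nonzero relative abundances, in nats by
    default (``base`` switches the logarithm).
    """
    counts = table.counts.astype(float)
    sums = counts.sum(axis=1)
    _check_positive_rows(pd.Series(sums, index=table.sample_ids))
    p = counts / sums[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1) / math.log(base)
    richness = (counts > 0).sum(axis=1)
    df = pd.DataFrame(
        {"richness": richness, "shannon": shannon},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )
    return AlphaDiversity(df)
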