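"""Feature-table and metadata I/O, rarefaction, and taxonomic aggregation.

On-disk conventions follow the classic QIIME layout: the feature table is a
tab-separated file with taxa as rows and samples as columns; sample metadata
is a CSV with one row per sample. In memory the feature table is oriented
samples x taxa, which is what every downstream statistic consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_METADATA_COLUMNS = (
    "glacier_id",
    "continent",
    "lat",
    "lon",
    "hdi",
    "u",
    "msr",
    "mmt",
    "tmp",
    "vp",
)

#: Environmental / anthropogenic covariates used in driver attribution.
COVARIATE_COLUMNS = ("lat", "lon", "hdi", "u", "msr", "mmt", "tmp", "vp")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class FeatureTable:
    """Counts of taxa per sample.

    Parameters
    ----------
    counts
        Non-negative integer matrix, samples as rows, taxa as columns.
    taxonomy
        Optional taxon annotation, indexed by taxon id, with columns such as
        ``phylum`` and ``genus``. Taxa missing from the map are treated as
        ``Unclassified`` during aggregation.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon ids: {dups}")
        arr = c.to_numpy()
        if np.issubdtype(arr.dtype, np.floating):
            if np.isnan(arr).any():
                raise FormatError("feature table contains NaN cells")
            if not np.array_equal(arr, np.floor(arr)):
                raise FormatError("feature table counts must be integers")
            c = c.astype(np.int64)
        elif not np.issubdtype(arr.dtype, np.integer):
            raise FormatError(f"feature table counts must be numeric, got {arr.dtype}")
        if (c.to_numpy() < 0).any():
            raise FormatError("feature table counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def filter_samples(self, keep: list[str]) -> "FeatureTable":
        return FeatureTable(self.counts.loc[keep], self.taxonomy)

    def drop_empty_taxa(self) -> "FeatureTable":
        nonzero = self.counts.columns[(self.counts > 0).any(axis=0)]
        return FeatureTable(self.counts[nonzero], self.taxonomy)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            empty = list(totals.index[totals == 0])
            raise FormatError(f"all-zero samples have undefined proportions: {empty}")
        return self.counts.div(totals, axis=0)


def read_feature_table(path, taxonomy: pd.DataFrame | None = None) -> FeatureTable:
    """Read a taxa-rows x sample-columns TSV into a :class:`FeatureTable`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dups = [c for c in header[1:] if header[1:].count(c) > 1]
    if dups:
        raise FormatError(f"duplicate sample column(s) in {path}: {sorted(set(dups))}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate taxon row(s) in {path}: {dups}")
    try:
        numeric = raw.apply(pd.to_numeric)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    return FeatureTable(numeric.T, taxonomy=taxonomy)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write taxa-as-rows TSV (the transpose of the in-memory orientation)."""
    out = table.counts.T
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read the per-sample metadata CSV and validate ranges."""
    md = pd.read_csv(path, index_col="sample_id")
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    if md.index.has_duplicates:
        raise FormatError("duplicate sample ids in metadata")
    validate_coordinates(md["lat"], md["lon"])
    hdi = md["hdi"].to_numpy(dtype=float)
    if np.isnan(hdi).any() or (hdi < 0).any() or (hdi > 1).any():
        raise FormatError("hdi must lie in [0, 1]")
    return md


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


def validate_coordinates(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.isnan(lat).any() or (np.abs(lat) > 90).any():
        raise ValueError("latitude out of range [-90, 90]")
    if np.isnan(lon).any() or (lon <= -180).any() or (lon > 180).any():
        raise ValueError("longitude out of range (-180, 180]")


@dataclass
class RarefactionResult:
    """Rarefied table plus the ids of samples that were too shallow to keep."""

    table: FeatureTable
    depth: int
    dropped_samples: list[str] = field(default_factory=list)


def rarefy(table: FeatureTable, depth: int | None = None, seed: int = 0) -> RarefactionResult:
    """Subsample every sample without replacement to a uniform depth.

    Samples whose total count is below ``depth`` are dropped and reported.
    ``depth=None`` uses the minimum sample sum of the input table, so no
    sample is dropped. Subsampling is multivariate-hypergeometric (drawing
    reads without replacement), the standard rarefaction model.
    """
    sums = table.sample_sums
    if depth is None:
        depth = int(sums.min())
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    kept, rows, dropped = [], [], []
    for sample_id, row in table.counts.iterrows():
        total = int(row.sum())
        if total < depth:
            dropped.append(sample_id)
            continue
        kept.append(sample_id)
        rows.append(rng.multivariate_hypergeometric(row.to_numpy(), depth))
    if not kept:
        raise ValueError(f"no sample reaches depth {depth}")
    counts = pd.DataFrame(np.asarray(rows), index=kept, columns=table.counts.columns)
    return RarefactionResult(FeatureTable(counts, table.taxonomy), depth, dropped)


def aggregate_relative_abundance(
    table: FeatureTable,
    taxonomy: pd.DataFrame | None = None,
    rank: str = "phylum",
) -> pd.DataFrame:
    """Collapse taxa to a taxonomic rank and return per-sample proportions.

    Taxa absent from the taxonomy map (or with a null label) are pooled into
    an ``Unclassified`` bucket. Samples with zero total are excluded with a
    warning because their proportions are undefined.
    """
    taxonomy = taxonomy if taxonomy is not None else table.taxonomy
    if taxonomy is not None and rank in taxonomy.columns:
        labels = taxonomy[rank].reindex(table.taxon_ids)
    else:
        labels = pd.Series(index=table.taxon_ids, dtype=object)
    labels = labels.fillna("Unclassified").astype(str)

    totals = table.sample_sums
    empty = list(totals.index[totals == 0])
    if empty:
        warnings.warn(f"excluding all-zero samples from aggregation: {empty}", stacklevel=2)
    counts = table.counts.loc[totals > 0]
    grouped = counts.T.groupby(labels.to_numpy()).sum().T
    return grouped.div(grouped.sum(axis=1), axis=0)
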