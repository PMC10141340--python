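"""Feature tables, metadata, and the table dialects used by the pipeline.

The common currency of every stage is a :class:`FeatureTable`: a samples ×
features matrix of non-negative values — GC–MS peak areas for breath VOCs,
relative-abundance fractions for taxa — with ordered, unique identifiers on
both axes.  Readers exist for two dialects: a plain tab-separated VOC table
(samples in rows by default) and the merged taxonomic-profile dialect with
pipe-delimited lineage strings (``k__...|p__...|...|s__...``) in the first
column and one abundance column per sample.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from skbio.stats.composition import clr as _skbio_clr
from skbio.stats.composition import multi_replace as _skbio_multi_replace

logger = logging.getLogger(__name__)

#: Lineage prefixes ordered from kingdom to strain, as used by merged
#: taxonomic profile tables.
RANK_PREFIXES = ("k", "p", "c", "o", "f", "g", "s", "t")
RANK_NAMES = {
    "kingdom": "k",
    "phylum": "p",
    "class": "c",
    "order": "o",
    "family": "f",
    "genus": "g",
    "species": "s",
    "strain": "t",
}


class TableError(ValueError):
    """Raised for malformed tables or contract violations on table operations."""


@dataclass
class FeatureTable:
    """Samples × features matrix with identifiers and per-feature annotation.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are features; values are finite and >= 0.
    kind : {"voc", "taxon"}
        Measurement modality; taxon tables hold relative-abundance fractions.
    feature_meta : dict
        Optional per-feature annotation (e.g. full taxonomy string).
    """

    data: pd.DataFrame
    kind: str
    feature_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("voc", "taxon"):
            raise TableError(f"unknown table kind {self.kind!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise TableError(f"duplicate sample ids: {dup}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise TableError(f"duplicate feature ids: {dup}")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise TableError("non-finite values in feature table")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise TableError(
                f"negative value at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.kind, dict(self.feature_meta))

    def to_tsv(self, path: str | Path) -> None:
        """Write the table tab-separated, samples in rows, UTF-8."""
        self.data.to_csv(path, sep="\t", index_label="sample_id", encoding="utf-8")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.array_equal(self.data.to_numpy(), other.data.to_numpy())
        )


@dataclass
class SampleMetadata:
    """Per-sample annotation: required group label plus free covariates."""

    table: pd.DataFrame  # indexed by sample_id, must contain column "group"

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise TableError("metadata must contain a 'group' column")
        if self.table.index.duplicated().any():
            raise TableError("duplicate sample ids in metadata")
        if self.table["group"].isna().any():
            missing = self.table.index[self.table["group"].isna()].tolist()
            raise TableError(f"samples without group label: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def group_sizes(self) -> dict[str, int]:
        return self.table["group"].value_counts().to_dict()


@dataclass
class StudyDataset:
    """Sample-aligned VOC and taxon tables with shared metadata."""

    voc: FeatureTable
    taxa: FeatureTable
    metadata: SampleMetadata

    def __post_init__(self) -> None:
        ids = self.voc.sample_ids
        if self.taxa.sample_ids != ids or self.metadata.sample_ids != ids:
            raise TableError("voc, taxa and metadata must share identical sample order")
        if len(ids) < 3:
            raise TableError(f"need at least 3 samples, got {len(ids)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.voc.sample_ids

    def subset_group(self, group: str) -> "StudyDataset":
        """Restrict the dataset to samples carrying one group label."""
        mask = self.metadata.groups == group
        if int(mask.sum()) == 0:
            raise TableError(f"no samples in group {group!r}")
        keep = self.metadata.table.index[mask]
        return StudyDataset(
            FeatureTable(self.voc.data.loc[keep], "voc", dict(self.voc.feature_meta)),
            FeatureTable(self.taxa.data.loc[keep], "taxon", dict(self.taxa.feature_meta)),
            SampleMetadata(self.metadata.table.loc[keep]),
        )


# ---------------------------------------------------------------------------
# readers


def _check_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.any().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise TableError(
            f"{path}: non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return coerced


def read_voc_table(path: str | Path, orientation: str = "samples-in-rows") -> FeatureTable:
    """Read a tab-separated VOC peak-area table.

    Missing cells are below-detection peaks and read as zero.  With
    ``orientation="features-in-rows"`` the file is transposed after reading,
    so the two dialects are involutions of one another.
    """
    if orientation not in ("samples-in-rows", "features-in-rows"):
        raise TableError(f"unknown orientation {orientation!r}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    cols = header[1:]
    if len(cols) != len(set(cols)):
        dup = sorted({c for c in cols if cols.count(c) > 1})
        raise TableError(f"{path}: duplicate header columns {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise TableError(f"{path}: no feature columns")
    df = _check_numeric(df, path)
    df = df.fillna(0.0)
    if orientation == "features-in-rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        raise TableError(f"{path}: duplicate sample ids")
    if df.columns.duplicated().any():
        raise TableError(f"{path}: duplicate compound columns")
    return FeatureTable(df, "voc")


def _parse_lineage(lineage: str) -> list[tuple[str, str]]:
    parts = []
    for seg in lineage.split("|"):
        if "__" not in seg:
            raise TableError(f"taxonomy string without rank prefix: {lineage!r}")
        prefix, name = seg.split("__", 1)
        if prefix not in RANK_PREFIXES:
            raise TableError(f"unknown rank prefix {prefix!r} in {lineage!r}")
        parts.append((prefix, name))
    return parts


def read_taxon_profiles(path: str | Path, rank: str = "species") -> FeatureTable:
    """Read a merged taxonomic-profile table and extract one rank.

    Rows are keyed by a pipe-delimited lineage string; one abundance column
    per sample, in percent or fraction.  Only rows terminating exactly at the
    requested rank are retained; percent tables are rescaled to fractions and
    every sample is renormalized to sum to one.  Lines starting with ``#``
    are comments.
    """
    if rank not in RANK_NAMES:
        raise TableError(f"unknown rank {rank!r}; choose from {sorted(RANK_NAMES)}")
    prefix = RANK_NAMES[rank]
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise TableError(f"{path}: empty profile table")
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise TableError(f"{path}: no sample columns")
    df = _check_numeric(df, path).fillna(0.0)

    keep_rows: list[str] = []
    short_names: list[str] = []
    meta: dict[str, dict] = {}
    for lineage in df.index.astype(str):
        parts = _parse_lineage(lineage)
        if parts[-1][0] == prefix:
            keep_rows.append(lineage)
            short_names.append(parts[-1][1])
    if not keep_rows:
        raise TableError(f"{path}: no rows at rank {rank!r}")

    # disambiguate short-name collisions with the parent segment of the lineage
    counts = pd.Series(short_names).value_counts()
    final_names = []
    for lineage, name in zip(keep_rows, short_names):
        if counts[name] > 1:
            parent = _parse_lineage(lineage)[-2][1] if "|" in lineage else lineage
            name = f"{name}|{parent}"
        final_names.append(name)
        meta[name] = {"lineage": lineage}

    sub = df.loc[keep_rows].T  # samples × taxa
    sub.columns = final_names
    values = sub.to_numpy(dtype=float)
    # percent dialect: per-sample sums near 100 rather than near 1
    if np.nanmax(values.sum(axis=1)) > 1.5:
        values = values / 100.0
    sums = values.sum(axis=1)
    nonzero = sums > 0
    values[nonzero] = values[nonzero] / sums[nonzero, None]
    out = pd.DataFrame(values, index=sub.index.astype(str), columns=final_names)
    return FeatureTable(out, "taxon", meta)


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a metadata TSV with columns ``sample_id`` and ``group``."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return SampleMetadata(df)


# ---------------------------------------------------------------------------
# filters and transforms


def prevalence_filter(
    table: FeatureTable,
    min_fraction: float,
    presence_rule: Callable[[np.ndarray], np.ndarray] | None = None,
) -> FeatureTable:
    """Keep features present in at least ``min_fraction`` of samples.

    Presence defaults to a strictly positive value; the boundary is
    inclusive (``count / n >= min_fraction``).  Feature order is preserved
    and the sample set is unchanged.
    """
    if not 0 < min_fraction <= 1:
        raise TableError(f"min_fraction must be in (0, 1], got {min_fraction}")
    values = table.data.to_numpy()
    present = presence_rule(values) if presence_rule is not None else values > 0
    counts = present.sum(axis=0)
    n = table.n_samples
    # small tolerance so e.g. 3/10 passes min_fraction=0.3 despite float repr
    keep = counts / n >= min_fraction - 1e-12
    if not keep.any():
        raise TableError(
            f"prevalence filter at {min_fraction} removed all "
            f"{table.n_features} features (n={n} samples)"
        )
    kept_cols = [c for c, k in zip(table.data.columns, keep) if k]
    meta = {k: v for k, v in table.feature_meta.items() if k in set(kept_cols)}
    return FeatureTable(table.data[kept_cols], table.kind, meta)


def transform_values(table: FeatureTable, method: str, **params) -> FeatureTable:
    """Apply a per-feature or per-sample value transform.

    Methods
    -------
    ``identity``
        Returns the values unchanged (bit-equal).
    ``log10_pseudo``
        log10(x + pseudo) with per-feature pseudo-count equal to half the
        smallest positive value of that feature (columns of all zeros use 1).
    ``zscore``
        Per-feature standardization to mean 0, sd 1 (ddof=0).
    ``clr_with_zero_replacement``
        Multiplicative zero replacement followed by the centered log-ratio,
        per sample.
    """
    values = table.data.to_numpy(dtype=float).copy()
    if method == "identity":
        out = values
    elif method == "log10_pseudo":
        pseudo = np.empty(values.shape[1])
        for j in range(values.shape[1]):
            pos = values[:, j][values[:, j] > 0]
            pseudo[j] = pos.min() / 2.0 if pos.size else 1.0
        out = np.log10(values + pseudo[None, :])
    elif method == "zscore":
        constant = np.ptp(values, axis=0) == 0
        if constant.any():
            j = int(np.argmax(constant))
            raise TableError(
                f"zscore undefined for constant feature {table.data.columns[j]!r}"
            )
        out = (values - values.mean(axis=0)) / values.std(axis=0, ddof=0)
    elif method == "clr_with_zero_replacement":
        sums = values.sum(axis=1)
        if (sums == 0).any():
            i = int(np.argmax(sums == 0))
            raise TableError(f"clr undefined for all-zero sample {table.data.index[i]!r}")
        comp = values / sums[:, None]
        if (comp == 0).any():
            comp = _skbio_multi_replace(comp)
        out = _skbio_clr(comp)
    else:
        raise TableError(f"unknown transform {method!r}")
    df = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    result = FeatureTable.__new__(FeatureTable)
    # transformed values may be negative; bypass the non-negativity contract
    result.data = df
    result.kind = table.kind
    result.feature_meta = dict(table.feature_meta)
    return result


def align_samples(
    voc: FeatureTable, taxa: FeatureTable, metadata: SampleMetadata
) -> StudyDataset:
    """Restrict all three inputs to their common samples, in a single order.

    Sample order follows the VOC table; dropped ids are logged.
    """
    common = [
        s
        for s in voc.sample_ids
        if s in set(taxa.sample_ids) and s in set(metadata.sample_ids)
    ]
    if not common:
        raise TableError("no samples shared between voc, taxa and metadata")
    all_ids = set(voc.sample_ids) | set(taxa.sample_ids) | set(metadata.sample_ids)
    dropped = sorted(all_ids - set(common))
    if dropped:
        logger.warning("align_samples dropped %d sample(s): %s", len(dropped), dropped)
    return StudyDataset(
        FeatureTable(voc.data.loc[common], "voc", dict(voc.feature_meta)),
        FeatureTable(taxa.data.loc[common], "taxon", dict(taxa.feature_meta)),
        SampleMetadata(metadata.table.loc[common]),
    )
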