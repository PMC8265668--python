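"""Feature-table and sample-metadata containers and I/O.

The central object is :class:`FeatureTable`, a thin validated wrapper around a
``pandas.DataFrame`` of non-negative integer counts with amplicon sequence
variants (ASVs, or externally clustered OTUs) as rows and samples as columns.
Sample roles (negative control vs experimental), data-set and tissue labels
live in :class:`SampleMetadata` and drive every downstream subsetting step.

Depth normalization is rarefaction: random subsampling without replacement to
a fixed number of reads per sample (multivariate hypergeometric draw), so a
rarefied count can never exceed the original count and column totals are
exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    IdentifierError,
    MetadataError,
    ValidationError,
)

logger = logging.getLogger(__name__)

ROLE_CONTROL = "control"
ROLE_EXPERIMENTAL = "experimental"
_VALID_ROLES = frozenset({ROLE_CONTROL, ROLE_EXPERIMENTAL})

REQUIRED_METADATA_COLUMNS = ("sample_id", "role", "dataset", "tissue")


class FeatureTable:
    """Validated features x samples count matrix.

    Parameters
    ----------
    counts
        DataFrame with feature identifiers as the index and sample
        identifiers as columns; values must be non-negative integers.
    drop_empty_samples
        Whether all-zero sample columns are dropped (default, logged) or
        kept with a warning.
    """

    def __init__(self, counts: pd.DataFrame, *, drop_empty_samples: bool = True):
        if counts.shape[0] == 0 or counts.shape[1] == 0:
            raise FormatError("feature table is empty")
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate feature identifiers: {dups}")
        if counts.columns.duplicated().any():
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate sample identifiers: {dups}")

        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("feature table contains non-numeric entries")
        if np.isnan(values.astype(float)).any():
            raise ValidationError("feature table contains missing values")
        if (values < 0).any():
            raise ValidationError("feature table contains negative counts")
        if not np.allclose(values, np.round(values.astype(float))):
            raise ValidationError("feature table contains fractional counts")

        df = counts.astype(np.int64)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)

        empty = df.columns[df.sum(axis=0) == 0]
        if len(empty):
            if drop_empty_samples:
                logger.info("dropping %d all-zero sample(s): %s", len(empty), list(empty))
                df = df.drop(columns=empty)
                if df.shape[1] == 0:
                    raise ValidationError("all samples are empty")
            else:
                logger.warning("keeping %d all-zero sample(s): %s", len(empty), list(empty))

        self._df = df

    # -- accessors ---------------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        """Underlying counts (features x samples, int64). Do not mutate."""
        return self._df

    @property
    def feature_ids(self) -> list[str]:
        return self._df.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._df.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def sample_totals(self) -> pd.Series:
        return self._df.sum(axis=0)

    def feature_totals(self) -> pd.Series:
        return self._df.sum(axis=1)

    # -- derived tables ----------------------------------------------------

    def select_samples(self, sample_ids) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self._df.columns]
        if missing:
            raise IdentifierError(f"unknown sample identifiers: {missing}")
        return FeatureTable(self._df[list(sample_ids)], drop_empty_samples=False)

    def drop_features(self, feature_ids) -> "FeatureTable":
        keep = self._df.index.difference(pd.Index(list(feature_ids)), sort=False)
        if len(keep) == 0:
            raise ValidationError("dropping these features would empty the table")
        return FeatureTable(self._df.loc[keep], drop_empty_samples=False)

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"FeatureTable({self.shape[0]} features x {self.shape[1]} samples)"

    # -- I/O -----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self._df.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


def read_feature_table(path, orientation: str = "features_as_rows",
                       *, drop_empty_samples: bool = True) -> FeatureTable:
    """Read a TSV count table (identifiers in first column, header row)."""
    if orientation not in ("features_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path} contains no data")
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise ValidationError(f"{path} contains non-numeric counts")
    if orientation == "samples_as_rows":
        df = df.T
    return FeatureTable(df, drop_empty_samples=drop_empty_samples)


def read_biom_table(path, *, drop_empty_samples: bool = True) -> FeatureTable:
    """Read a BIOM-format table (sparse or dense) as an alternative entry point."""
    import biom  # deferred: only needed for BIOM inputs

    bt = biom.load_table(str(path))
    df = bt.to_dataframe(dense=True)  # features x samples
    return FeatureTable(df, drop_empty_samples=drop_empty_samples)


@dataclass
class SampleMetadata:
    """Per-sample role / data-set / tissue annotations.

    ``df`` is indexed by sample_id with at least the columns
    ``role`` (control|experimental), ``dataset`` and ``tissue``; extra
    grouping columns (species, feeding status, ...) are carried through.
    """

    df: pd.DataFrame

    def __post_init__(self):
        if self.df.index.duplicated().any():
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate sample_id in metadata: {dups}")
        for col in ("role", "dataset", "tissue"):
            if col not in self.df.columns:
                raise MetadataError(f"metadata is missing required column {col!r}")
        bad = set(self.df["role"].unique()) - _VALID_ROLES
        if bad:
            raise MetadataError(
                f"unknown role value(s) {sorted(bad)}; expected {sorted(_VALID_ROLES)}"
            )
        self.df.index = self.df.index.astype(str)

    @classmethod
    def from_tsv(cls, path) -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise MetadataError(f"metadata {path} is missing column(s) {missing}")
        return cls(df.set_index("sample_id"))

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @property
    def sample_ids(self) -> list[str]:
        return self.df.index.tolist()

    def samples(self, *, role: str | None = None, dataset: str | None = None,
                tissue: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.df.index)
        if role is not None:
            mask &= self.df["role"] == role
        if dataset is not None:
            mask &= self.df["dataset"] == dataset
        if tissue is not None:
            mask &= self.df["tissue"] == tissue
        return self.df.index[mask].tolist()

    def controls(self, dataset: str | None = None) -> list[str]:
        return self.samples(role=ROLE_CONTROL, dataset=dataset)

    def experimental(self, dataset: str | None = None, tissue: str | None = None) -> list[str]:
        return self.samples(role=ROLE_EXPERIMENTAL, dataset=dataset, tissue=tissue)

    @property
    def datasets(self) -> list[str]:
        return sorted(self.df["dataset"].unique())

    def validate_against(self, table: FeatureTable) -> None:
        """Every table sample must have exactly one metadata row; each dataset
        needs at least one control and one experimental sample for screening."""
        missing = [s for s in table.sample_ids if s not in self.df.index]
        if missing:
            raise MetadataError(f"samples without metadata: {missing}")
        sub = self.df.loc[table.sample_ids]
        for ds, grp in sub.groupby("dataset"):
            roles = set(grp["role"])
            if _VALID_ROLES - roles:
                raise MetadataError(
                    f"dataset {ds!r} lacks a "
                    f"{'control' if ROLE_CONTROL not in roles else 'experimental'} sample"
                )


@dataclass
class NormalizationConfig:
    """Rarefaction settings: target depth, RNG seed, and what to do with
    samples whose total is below the target (drop by default)."""

    depth: int = 25_000
    seed: int = 0
    drop_below_depth: bool = True

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


def filter_singletons(table: FeatureTable) -> FeatureTable:
    """Remove features whose total count across the whole table equals 1.

    Idempotent; all other counts are untouched. A singleton is defined on the
    data-set total, not per sample.
    """
    totals = table.feature_totals()
    keep = totals[totals != 1].index
    if len(keep) == 0:
        logger.warning("all features are singletons; result is empty")
        raise ValidationError("singleton filtering removed every feature")
    if len(keep) == len(totals):
        return table
    return FeatureTable(table.df.loc[keep], drop_empty_samples=False)


def subsample_to_depth(table: FeatureTable, config: NormalizationConfig) -> FeatureTable:
    """Rarefy every sample to ``config.depth`` reads without replacement.

    Samples already at exactly the target depth pass through unchanged.
    Samples below the target are dropped (default) or kept unchanged with a
    warning. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    depth = config.depth
    out = {}
    for sid in table.sample_ids:
        col = table.df[sid].to_numpy()
        total = int(col.sum())
        if total < depth:
            if config.drop_below_depth:
                logger.info("dropping sample %s: depth %d < %d", sid, total, depth)
                continue
            logger.warning("keeping sample %s below depth (%d < %d)", sid, total, depth)
            out[sid] = col
        elif total == depth:
            out[sid] = col
        else:
            out[sid] = rng.multivariate_hypergeometric(col, depth)
    if not out:
        logger.warning("no sample reached depth %d; rarefied table is empty", depth)
        raise ValidationError(f"no sample has >= {depth} reads")
    df = pd.DataFrame(out, index=table.df.index)
    return FeatureTable(df, drop_empty_samples=False)
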