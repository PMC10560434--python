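"""Feature tables, taxonomy maps and sample metadata.

The canonical in-memory container is :class:`FeatureTable`, a thin wrapper
around a samples-in-rows :class:`pandas.DataFrame` that tracks a
normalization state (``raw``, ``rarefied``, ``css`` or ``clr``).  The
module also implements the preprocessing rules used throughout the
analysis: dropping shallow samples, the abundance/prevalence pre-filter
for network construction, domain subsetting, per-sample relative
abundances of taxonomic groups, and shared/unique feature counts across
groups of tables (Venn-style membership patterns).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from estuarch.errors import EmptyResultError, FormatError

NormState = Literal["raw", "rarefied", "css", "clr"]

_COUNT_STATES = ("raw", "rarefied")


@dataclass
class FeatureTable:
    """Samples x features abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with sample identifiers as index and feature identifiers
        as columns.  Raw and rarefied tables must hold nonnegative
        integers; css tables nonnegative reals; clr tables are
        unrestricted reals.
    normalized:
        Normalization state flag.
    """

    data: pd.DataFrame
    normalized: NormState = "raw"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        values = self.data.to_numpy()
        if self.normalized != "clr" and values.size and np.nanmin(values) < 0:
            raise FormatError("negative values in a non-clr feature table")
        if self.normalized in _COUNT_STATES and values.size:
            if not np.allclose(values, np.round(values)):
                raise FormatError(
                    f"state {self.normalized!r} requires integer counts"
                )
            self.data = self.data.round().astype(np.int64)

    # -- accessors ---------------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

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

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def feature_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.normalized)

    # -- I/O ---------------------------------------------------------------
    def write_tsv(self, path: str | Path) -> None:
        """Write the table as TSV (samples in rows) with a sidecar state
        comment when the table is not raw counts."""
        path = Path(path)
        with open(path, "w") as fh:
            if self.normalized != "raw":
                fh.write(f"# normalized: {self.normalized}\n")
            self.data.rename_axis("sample_id").to_csv(fh, sep="\t")


def read_feature_table(
    path: str | Path,
    orientation: Literal["samples_in_rows", "features_in_rows"] = "samples_in_rows",
) -> FeatureTable:
    """Read a TSV feature table and validate it.

    A leading ``# normalized: <state>`` comment line records the
    normalization state; absent, the table is taken as raw counts.
    Features-in-rows files are transposed to the canonical samples-in-rows
    orientation.

    Raises
    ------
    FormatError
        On ragged rows, duplicate identifiers or negative values, naming
        the offending line/cell.
    """
    path = Path(path)
    state: NormState = "raw"
    skip = 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# normalized:"):
            state = first.split(":", 1)[1].strip().split()[0]  # type: ignore[assignment]
            skip = 1

    with open(path) as fh:
        lines = fh.readlines()[skip:]
    header = lines[0].rstrip("\n").split("\t")
    ncol = len(header)
    ids = header[1:]
    if len(set(ids)) != len(ids):
        dups = sorted({h for h in ids if ids.count(h) > 1})
        raise FormatError(f"{path.name}: duplicate header ids: {dups}")
    row_ids = [ln.split("\t", 1)[0] for ln in lines[1:] if ln.strip()]
    if len(set(row_ids)) != len(row_ids):
        dups = sorted({r for r in row_ids if row_ids.count(r) > 1})
        raise FormatError(f"{path.name}: duplicate row ids: {dups}")
    for lineno, line in enumerate(lines[1:], start=skip + 2):
        n = len(line.rstrip("\n").split("\t"))
        if n != ncol:
            raise FormatError(
                f"{path.name}:{lineno}: ragged row ({n} fields, expected {ncol})"
            )

    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = df.rename_axis(None, axis=0).rename_axis(None, axis=1)
    if orientation == "features_in_rows":
        df = df.T
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any() and not df.isna().any().any():
        bad = numeric.isna().stack()
        cell = bad[bad].index[0]
        raise FormatError(f"{path.name}: non-numeric value at {cell}")
    if state != "clr":
        neg = numeric < 0
        if neg.any().any():
            flat = neg.stack()
            sample, feature = flat[flat].index[0]
            raise FormatError(
                f"{path.name}: negative value at sample={sample!r} feature={feature!r}"
            )
    return FeatureTable(numeric, state)


@dataclass
class TaxonomyMap:
    """feature_id -> ranked lineage with derived domain flags.

    The ``domain`` column distinguishes archaea and bacteria; chloroplast
    features (16S of eukaryotic phytoplankton plastids) are flagged
    phytoplankton and excluded from the bacterial flag, so the three flags
    are mutually exclusive.
    """

    df: pd.DataFrame  # index feature_id; columns domain..genus

    RANKS = ("domain", "phylum", "class", "order", "family", "genus")

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise FormatError("duplicate feature ids in taxonomy")
        missing = [r for r in self.RANKS if r not in self.df.columns]
        if missing:
            raise FormatError(f"taxonomy missing ranks: {missing}")

    def _has_rank_value(self, value: str) -> pd.Series:
        hit = pd.Series(False, index=self.df.index)
        for rank in self.RANKS:
            hit |= self.df[rank].astype(str).str.casefold() == value.casefold()
        return hit

    @property
    def is_phytoplankton(self) -> pd.Series:
        """Chloroplast sequences profile photosynthetic protists."""
        return self._has_rank_value("Chloroplast")

    @property
    def is_archaeon(self) -> pd.Series:
        return (self.df["domain"].astype(str).str.casefold() == "archaea") & ~self.is_phytoplankton

    @property
    def is_bacterium(self) -> pd.Series:
        return (self.df["domain"].astype(str).str.casefold() == "bacteria") & ~self.is_phytoplankton

    def flag(self, name: str) -> pd.Series:
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(f"unknown domain flag {name!r}") from None

    def lineage(self, feature_id: str) -> tuple[str, ...]:
        return tuple(self.df.loc[feature_id, list(self.RANKS)])

    def write_tsv(self, path: str | Path) -> None:
        self.df.rename_axis("feature_id").to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return TaxonomyMap(df)


@dataclass
class SampleMetadata:
    """Per-sample design factors and environmental covariates.

    ``factors`` lists the categorical design columns (estuary, season,
    station, ...); the remaining numeric columns are treated as
    environmental covariates.  Missing covariate values are allowed here;
    the network module rejects them.
    """

    df: pd.DataFrame  # index sample_id
    factors: tuple[str, ...] = ("estuary", "season", "station")

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        missing = [f for f in self.factors if f not in self.df.columns]
        if missing:
            raise FormatError(f"metadata missing factor columns: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def env_columns(self) -> list[str]:
        return [
            c
            for c in self.df.columns
            if c not in self.factors and pd.api.types.is_numeric_dtype(self.df[c])
        ]

    def env_table(self, names: Iterable[str] | None = None) -> pd.DataFrame:
        names = list(names) if names is not None else self.env_columns
        return self.df[names].copy()

    def write_tsv(self, path: str | Path) -> None:
        self.df.rename_axis("sample_id").to_csv(path, sep="\t")


def read_metadata(
    path: str | Path, factors: tuple[str, ...] = ("estuary", "season", "station")
) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df, factors)


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def drop_low_depth_samples(table: FeatureTable, min_reads: int = 100) -> FeatureTable:
    """Remove samples whose total read count is strictly below ``min_reads``.

    Mirrors the convention of discarding samples with < 100 reads of the
    focal domain before normalization; the boundary is strict, so a sample
    with exactly ``min_reads`` reads is retained.
    """
    if table.normalized not in _COUNT_STATES:
        raise ValueError("drop_low_depth_samples expects raw/rarefied counts")
    keep = table.sample_sums() >= min_reads
    if not keep.any():
        raise EmptyResultError(
            f"every sample has fewer than {min_reads} reads"
        )
    return FeatureTable(table.data.loc[keep], table.normalized)


def filter_for_network(
    table: FeatureTable, min_total: int = 100, min_prevalence: float = 0.15
) -> FeatureTable:
    """Abundance/prevalence pre-filter applied before network inference.

    A feature is retained iff its total read count across samples is
    >= ``min_total`` AND it is nonzero in at least
    ``ceil(min_prevalence * n_samples)`` samples.  Both boundaries are
    inclusive.  This reduces compositional artefacts and spurious
    associations from rare, sporadic taxa.
    """
    if table.normalized not in _COUNT_STATES:
        raise ValueError("filter_for_network expects raw/rarefied counts")
    n = table.n_samples
    min_samples = int(np.ceil(min_prevalence * n))
    totals = table.feature_sums()
    prevalence = (table.data > 0).sum(axis=0)
    keep = (totals >= min_total) & (prevalence >= min_samples)
    if not keep.any():
        warnings.warn("filter_for_network removed every feature", stacklevel=2)
    return FeatureTable(table.data.loc[:, keep], table.normalized)


def subset_by_domain(
    table: FeatureTable, taxonomy: TaxonomyMap, domain_flag: str
) -> FeatureTable:
    """Restrict columns to features carrying the given taxonomy flag
    (``is_archaeon``, ``is_bacterium`` or ``is_phytoplankton``)."""
    missing = [f for f in table.feature_ids if f not in taxonomy.df.index]
    if missing:
        raise KeyError(f"features missing from taxonomy: {missing[:10]}")
    flag = taxonomy.flag(domain_flag)
    keep = [f for f in table.feature_ids if bool(flag.loc[f])]
    return FeatureTable(table.data.loc[:, keep], table.normalized)


def relative_abundance_of(
    table: FeatureTable,
    taxonomy: TaxonomyMap,
    group: Mapping[str, str] | Iterable[str],
    denominator: Literal["all_features", "flagged_subset"] = "all_features",
    denominator_flag: str = "is_archaeon",
) -> pd.Series:
    """Per-sample relative abundance of a taxonomic group.

    ``group`` is either an explicit iterable of feature ids, or a mapping
    of rank -> name (e.g. ``{"genus": "Nitrosopumilus"}``) selecting all
    features whose lineage matches every entry.  The denominator is the
    per-sample total over all features, or over the features carrying
    ``denominator_flag`` (e.g. archaeal reads only).  Samples with a zero
    denominator report a missing value.
    """
    if table.normalized not in _COUNT_STATES:
        raise ValueError("relative_abundance_of expects raw/rarefied counts")
    if isinstance(group, Mapping):
        mask = pd.Series(True, index=taxonomy.df.index)
        for rank, name in group.items():
            if rank not in TaxonomyMap.RANKS:
                raise KeyError(f"unknown rank {rank!r}")
            mask &= taxonomy.df[rank].astype(str) == name
        members = [f for f in table.feature_ids if f in mask.index and bool(mask.loc[f])]
    else:
        members = [f for f in group]
        missing = [f for f in members if f not in table.feature_ids]
        if missing:
            raise KeyError(f"group features absent from table: {missing[:10]}")

    numer = table.data[members].sum(axis=1) if members else pd.Series(0.0, index=table.data.index)
    if denominator == "all_features":
        denom = table.sample_sums()
    else:
        flagged = taxonomy.flag(denominator_flag)
        cols = [f for f in table.feature_ids if bool(flagged.get(f, False))]
        denom = table.data[cols].sum(axis=1)
    out = numer / denom.replace(0, np.nan)
    out.name = "relative_abundance"
    return out.astype(float)


def shared_feature_counts(
    tables_by_group: Mapping[str, FeatureTable],
) -> dict[frozenset[str], int]:
    """Venn-style membership pattern counts across groups of tables.

    A feature is "present" in a group when it is nonzero in at least one
    sample of that group's table.  For every nonempty subset of groups the
    result maps the subset to the number of features present in exactly
    those groups; the counts partition the union of present features.
    """
    if len(tables_by_group) < 2:
        raise ValueError("need at least two groups")
    present: dict[str, set[str]] = {
        name: set(tab.data.columns[(tab.data > 0).any(axis=0)])
        for name, tab in tables_by_group.items()
    }
    names = list(present)
    counts: dict[frozenset[str], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(present[g] for g in combo))
            outside = set().union(*(present[g] for g in names if g not in combo))
            counts[frozenset(combo)] = len(inside - outside)
    return counts
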