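"""Gene-abundance tables, study metadata, and the functional hierarchy.

The central exchange object is :class:`GeneTable`, a thin immutable wrapper
around a pandas DataFrame in canonical genes × samples orientation holding
non-negative relative abundances (KO-style gene identifiers as row keys, as
exported by PICRUSt/PICRUSt2/Tax4Fun and HUMAnN2 KO regrouping).

File formats are plain TSV: tab-separated, UTF-8, lines starting with ``#``
ignored; the first field of the header row is an ID-column label and is
skipped.  Metadata files have two columns (sample_id, group); hierarchy
files have three (gene_id, level1, level2), one row per (gene,
category-pair) so a KO may map to several categories.
"""

from __future__ import annotations

import os
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneTable",
    "StudyMetadata",
    "FunctionalHierarchy",
    "AlignedPair",
    "read_gene_table",
    "write_gene_table",
    "read_metadata",
    "write_metadata",
    "read_hierarchy",
    "write_hierarchy",
    "normalize",
    "detected_genes",
    "align_pair",
    "aggregate_by_category",
]

#: absolute tolerance for floating comparisons throughout the package
ATOL = 1e-9

UNCLASSIFIED = "Unclassified"


@dataclass(frozen=True)
class GeneTable:
    """A genes × samples matrix of non-negative abundances.

    Row index holds gene IDs, columns hold sample IDs; both must be unique.
    Values are dimensionless (raw counts or relative abundances); call
    :func:`normalize` to obtain per-sample proportions summing to 1.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise TypeError("GeneTable.data must be a pandas DataFrame")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].tolist()[0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].tolist()[0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        df = df.copy()
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.to_numpy()][0]
                raise ValueError(
                    f"non-numeric value {df.loc[gene, col]!r} at gene {gene!r}, "
                    f"sample {col!r}"
                )
            df[col] = coerced
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value {values[i, j]} at gene {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )
        object.__setattr__(self, "data", df.astype(float))

    # -- convenience accessors -------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def restrict(
        self,
        genes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "GeneTable":
        """Subset (and reorder) to the given gene and/or sample IDs."""
        df = self.data
        if genes is not None:
            missing = [g for g in genes if g not in df.index]
            if missing:
                raise KeyError(f"genes not in table: {missing[:5]}")
            df = df.loc[list(genes)]
        if samples is not None:
            missing = [s for s in samples if s not in df.columns]
            if missing:
                raise KeyError(f"samples not in table: {missing[:5]}")
            df = df[list(samples)]
        return GeneTable(df)

    def equals(self, other: "GeneTable", atol: float = 1e-12) -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.values, other.values, atol=atol, rtol=0.0)
        )


@dataclass(frozen=True)
class StudyMetadata:
    """Sample → group assignment for a two-level categorical factor.

    ``group_labels`` declares the (group1, group2) ordering used for the
    sign of mean differences; swapping it flips every signed statistic.
    """

    assignments: Mapping[str, str]
    group_labels: tuple[str, str]

    def __post_init__(self) -> None:
        g1, g2 = self.group_labels
        if g1 == g2:
            raise ValueError("group labels must be distinct")
        labels = set(self.group_labels)
        extra = {g for g in self.assignments.values() if g not in labels}
        if extra:
            raise ValueError(f"assignment to undeclared group(s): {sorted(extra)}")
        for lab in self.group_labels:
            if not any(v == lab for v in self.assignments.values()):
                raise ValueError(f"group {lab!r} has no samples")
        object.__setattr__(self, "assignments", dict(self.assignments))

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == label]

    def group_of(self, sample: str) -> str:
        try:
            return self.assignments[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} has no group assignment") from None

    def group_mask(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Boolean mask over ``sample_ids``: True where sample is in group1."""
        return np.array(
            [self.group_of(s) == self.group_labels[0] for s in sample_ids],
            dtype=bool,
        )

    def swapped(self) -> "StudyMetadata":
        """Same assignments with the declared group order reversed."""
        return StudyMetadata(self.assignments, (self.group_labels[1], self.group_labels[0]))


@dataclass(frozen=True)
class FunctionalHierarchy:
    """Gene → set of (level-1, level-2) category pairs (KEGG-style, multi-mapped)."""

    entries: Mapping[str, frozenset[tuple[str, str]]]

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[tuple[str, str]]] = {}
        for gene, pairs in self.entries.items():
            fs = frozenset((str(l1), str(l2)) for l1, l2 in pairs)
            for l1, l2 in fs:
                if not l1 or not l2:
                    raise ValueError(f"empty category name for gene {gene!r}")
            clean[str(gene)] = fs
        object.__setattr__(self, "entries", clean)

    def categories(self, level: int = 2) -> list[str]:
        idx = _level_index(level)
        return sorted({pair[idx] for pairs in self.entries.values() for pair in pairs})

    def category_map(self, level: int = 2) -> dict[str, set[str]]:
        """Category name → set of member genes at the given level."""
        idx = _level_index(level)
        out: dict[str, set[str]] = {}
        for gene, pairs in self.entries.items():
            for pair in pairs:
                out.setdefault(pair[idx], set()).add(gene)
        return out

    def annotate(self, gene: str) -> frozenset[tuple[str, str]]:
        return self.entries.get(gene, frozenset())


def _level_index(level: int) -> int:
    if level not in (1, 2):
        raise ValueError("hierarchy level must be 1 or 2")
    return level - 1


@dataclass(frozen=True)
class AlignedPair:
    """Predicted and observed tables on a common sample set.

    Both member tables are restricted to ``shared_samples`` (identical
    ordering) but keep their full gene sets and whatever normalization they
    came with: restriction to ``shared_genes`` happens at statistic time,
    never to the composition itself.
    """

    predicted: GeneTable
    observed: GeneTable
    shared_genes: list[str] = field(default_factory=list)
    shared_samples: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)


def read_gene_table(
    path: str | os.PathLike, orientation: str = "genes_as_rows"
) -> GeneTable:
    """Read a gene-abundance TSV into canonical genes × samples orientation.

    ``orientation='samples_as_rows'`` transposes on read, so a table written
    either way round yields the identical :class:`GeneTable`.
    """
    if orientation not in ("genes_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path)
    if orientation == "samples_as_rows":
        df = df.T
    return GeneTable(df)


def write_gene_table(table: GeneTable, path: str | os.PathLike) -> None:
    table.data.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(
    path: str | os.PathLike, group_order: tuple[str, str] | None = None
) -> StudyMetadata:
    """Read a two-column sample_id / group TSV.

    Without an explicit ``group_order`` the declared (group1, group2)
    ordering follows first appearance in the file.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("metadata TSV needs at least two columns")
    samples = df.iloc[:, 0].astype(str)
    groups = df.iloc[:, 1].astype(str)
    if samples.duplicated().any():
        dup = samples[samples.duplicated()].iloc[0]
        raise ValueError(f"duplicate sample id in metadata: {dup!r}")
    assignments = dict(zip(samples, groups))
    seen = list(dict.fromkeys(groups))
    if group_order is None:
        if len(seen) != 2:
            raise ValueError(f"expected exactly two groups, found {seen}")
        group_order = (seen[0], seen[1])
    return StudyMetadata(assignments, tuple(group_order))


def write_metadata(metadata: StudyMetadata, path: str | os.PathLike) -> None:
    rows = [(s, g) for s, g in metadata.assignments.items()]
    pd.DataFrame(rows, columns=["sample_id", "group"]).to_csv(
        path, sep="\t", index=False
    )


def read_hierarchy(path: str | os.PathLike) -> FunctionalHierarchy:
    """Read a gene_id / level1 / level2 TSV (one row per category pair)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError("hierarchy TSV needs at least three columns")
    entries: dict[str, set[tuple[str, str]]] = {}
    for gene, l1, l2 in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]):
        entries.setdefault(str(gene), set()).add((str(l1), str(l2)))
    return FunctionalHierarchy(entries)


def write_hierarchy(hierarchy: FunctionalHierarchy, path: str | os.PathLike) -> None:
    rows = [
        (gene, l1, l2)
        for gene, pairs in hierarchy.entries.items()
        for l1, l2 in sorted(pairs)
    ]
    pd.DataFrame(rows, columns=["gene_id", "level1", "level2"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def normalize(table: GeneTable) -> GeneTable:
    """Scale each sample column to sum to 1 (zero entries stay zero).

    Idempotent; a sample with no positive abundance is rejected by name.
    """
    sums = table.values.sum(axis=0)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise ValueError(f"sample {table.sample_ids[zero[0]]!r} has zero total abundance")
    return GeneTable(table.data / sums)


def detected_genes(table: GeneTable, min_prevalence: int = 1) -> set[str]:
    """Genes with abundance > 0 in at least ``min_prevalence`` samples."""
    if min_prevalence < 1:
        raise ValueError("min_prevalence must be >= 1")
    counts = (table.values > 0).sum(axis=1)
    return {g for g, c in zip(table.gene_ids, counts) if c >= min_prevalence}


def align_pair(
    predicted: GeneTable, observed: GeneTable, min_prevalence: int = 1
) -> AlignedPair:
    """Intersect two tables' detected genes and sample sets.

    Both tables are restricted to the shared samples (ordering taken from the
    observed table); gene sets are left intact and the shared-gene list is
    recorded separately, preserving each method's own composition.
    """
    pred_samples = set(predicted.sample_ids)
    shared_samples = [s for s in observed.sample_ids if s in pred_samples]
    if not shared_samples:
        raise ValueError("no samples shared between predicted and observed tables")
    dp = detected_genes(predicted, min_prevalence)
    do = detected_genes(observed, min_prevalence)
    shared_genes = [g for g in observed.gene_ids if g in dp and g in do]
    if not shared_genes:
        raise ValueError("no detected genes shared between predicted and observed tables")
    return AlignedPair(
        predicted=predicted.restrict(samples=shared_samples),
        observed=observed.restrict(samples=shared_samples),
        shared_genes=shared_genes,
        shared_samples=shared_samples,
    )


def aggregate_by_category(
    table: GeneTable, hierarchy: FunctionalHierarchy, level: int = 1
) -> GeneTable:
    """Sum gene abundances into functional categories at the given level.

    A multi-mapped gene contributes its full abundance to each of its
    categories (KEGG BRITE double-counting convention), so category columns
    may sum to more than the sample total.  Genes without any annotation
    aggregate into an ``"Unclassified"`` row.
    """
    idx = _level_index(level)
    cats_per_gene: list[list[str]] = []
    for gene in table.gene_ids:
        pairs = hierarchy.annotate(gene)
        cats = sorted({pair[idx] for pair in pairs}) if pairs else [UNCLASSIFIED]
        cats_per_gene.append(cats)
    all_cats = sorted({c for cats in cats_per_gene for c in cats})
    out = np.zeros((len(all_cats), table.n_samples))
    cat_row = {c: i for i, c in enumerate(all_cats)}
    values = table.values
    for gi, cats in enumerate(cats_per_gene):
        for c in cats:
            out[cat_row[c]] += values[gi]
    return GeneTable(pd.DataFrame(out, index=all_cats, columns=table.sample_ids))
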