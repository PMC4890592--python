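"""Domain types and text-format IO for expression matrices, annotations and gene maps.

Matrices are stored genes-as-rows, samples-as-columns (the prevalent microarray
convention), on log2-intensity scale as produced by RMA-style normalisation.
Missing values are rejected rather than imputed: the decomposition identities
downstream (projected + residual = centered data) only hold on complete data.
Identifiers are compared case-sensitively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "GeneMapping",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_mapping",
    "map_genes",
]


class ParseError(ValueError):
    """A text input could not be parsed into a valid domain object."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise ParseError(f"duplicate {what} identifier: {i!r}")
            seen.add(i)


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression intensities.

    Attributes
    ----------
    values : ndarray, shape (n_genes, n_samples)
        Finite log2 intensities.
    gene_ids : list of str
        Unique row identifiers, in row order.
    sample_ids : list of str
        Unique column identifiers, in column order.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ParseError(
                f"non-finite value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_ids: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown gene identifier: {e.args[0]!r}") from None

    def sample_index(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown sample identifier: {e.args[0]!r}") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.sample_index(sample_ids)
        return ExpressionMatrix(self.values[:, idx], list(self.gene_ids), list(sample_ids))

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(gene_ids)
        return ExpressionMatrix(self.values[idx, :], list(gene_ids), list(self.sample_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleAnnotation:
    """Per-sample labels: fine group, large-scale group, optional sex and study."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("group", "large_scale_group")
    OPTIONAL = ("sex", "study_id")

    def __post_init__(self) -> None:
        t = self.table
        if t.index.name != "sample_id":
            if "sample_id" in t.columns:
                t = t.set_index("sample_id")
            else:
                raise ParseError("annotation requires a 'sample_id' column")
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ParseError(f"annotation requires a {col!r} column")
        if t.index.duplicated().any():
            dup = t.index[t.index.duplicated()][0]
            raise ParseError(f"duplicate sample identifier: {dup!r}")
        t.index = t.index.astype(str)
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def members(self, label: str, by: str = "group") -> list[str]:
        """Sample ids carrying ``label`` in column ``by``."""
        if by not in self.table.columns:
            raise KeyError(f"annotation has no column {by!r}")
        return list(self.table.index[self.table[by] == label])

    def group_sizes(self, by: str = "group") -> pd.Series:
        return self.table[by].value_counts()

    def restricted_to(self, sample_ids: Sequence[str]) -> "SampleAnnotation":
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples without annotation: {missing[:5]}")
        return SampleAnnotation(self.table.loc[list(sample_ids)].copy())


@dataclass
class GeneMapping:
    """Many-to-many (source_id, target_id) identifier pairs."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        cleaned = []
        for s, t in self.pairs:
            s, t = str(s), str(t)
            if not s or not t:
                raise ParseError("gene mapping contains an empty identifier")
            cleaned.append((s, t))
        self.pairs = cleaned

    @classmethod
    def identity(cls, gene_ids: Iterable[str]) -> "GeneMapping":
        return cls([(g, g) for g in gene_ids])


def read_expression(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples TSV (first row sample ids, first column gene ids)."""
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        raise ParseError(f"duplicate gene identifier: {df.index[df.index.duplicated()][0]!r}")
    if pd.Index(df.columns).duplicated().any():
        dup = pd.Index(df.columns)[pd.Index(df.columns).duplicated()][0]
        raise ParseError(f"duplicate sample identifier: {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | ~np.isfinite(numeric.to_numpy(dtype=float, na_value=np.nan))
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"missing or non-numeric value at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r} in {path}"
        )
    return ExpressionMatrix(numeric.to_numpy(dtype=float), list(df.index), list(df.columns))


def write_expression(x: ExpressionMatrix, path: str | Path) -> None:
    df = x.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_annotation(path: str | Path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleAnnotation(df)


def write_annotation(ann: SampleAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t")


def read_mapping(path: str | Path) -> GeneMapping:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source_id", "target_id"):
        if col not in df.columns:
            raise ParseError(f"mapping requires a {col!r} column")
    if df[["source_id", "target_id"]].isna().to_numpy().any():
        raise ParseError("gene mapping contains an empty identifier")
    return GeneMapping(list(zip(df["source_id"], df["target_id"])))


def map_genes(
    x: ExpressionMatrix, mapping: GeneMapping, ambiguous: str = "average"
) -> ExpressionMatrix:
    """Translate gene identifiers through a (possibly many-to-many) mapping.

    Sources mapping to the same target are averaged (``ambiguous="average"``)
    or the target is dropped entirely (``ambiguous="drop"``). A source feeding
    several targets contributes to each. Unmapped sources are dropped and
    targets are returned in lexicographic order.
    """
    if ambiguous not in ("average", "drop"):
        raise ValueError("ambiguous must be 'average' or 'drop'")
    lookup = {g: i for i, g in enumerate(x.gene_ids)}
    by_target: dict[str, list[int]] = {}
    for src, tgt in mapping.pairs:
        row = lookup.get(src)
        if row is not None:
            by_target.setdefault(tgt, []).append(row)
    if not by_target:
        raise ValueError("no common genes between matrix and mapping")
    targets = sorted(by_target)
    if ambiguous == "drop":
        targets = [t for t in targets if len(by_target[t]) == 1]
        if not targets:
            raise ValueError("no unambiguous genes after dropping multi-mapped targets")
    out = np.empty((len(targets), x.n_samples))
    for i, t in enumerate(targets):
        out[i] = x.values[by_target[t]].mean(axis=0)
    return ExpressionMatrix(out, targets, list(x.sample_ids))
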