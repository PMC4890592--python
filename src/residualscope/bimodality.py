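"""Kurtosis-based screening for bimodally expressed genes.

Contrasts with a small overall effect size but a large effect in a few genes
— typically genetic differences such as sex (XIST, Y-chromosomal genes) or
copy-number states — do not surface in the leading principal components.
They do, however, make the affected genes' expression distributions bimodal.
Low kurtosis flags bimodality: the moment-ratio kurtosis m4/m2^2 attains its
minimum of 1 for a balanced two-point distribution, is 3 for a normal one,
so ranking genes by ascending kurtosis surfaces two-mode genes first.

The raw moment ratio (no bias correction, no excess subtraction) is used;
alternative kurtosis variants are monotone transformations of each other for
fixed n, so the ranking — the quantity of interest — is unaffected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix

__all__ = ["BimodalityReport", "gene_kurtosis", "rank_bimodal", "split_by_gene"]


@dataclass
class BimodalityReport:
    """Ascending-kurtosis ranking over the screened (non-constant) genes."""

    table: pd.DataFrame  # columns: kurtosis, rank; index: gene_id, sorted by rank
    excluded: list[str]  # constant genes left out of the ranking
    top_n: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def top(self) -> pd.DataFrame:
        return self.table.head(self.top_n)


def gene_kurtosis(x: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Per-gene moment-ratio kurtosis m4 / m2^2 across samples.

    Requires at least 4 samples. Constant genes yield NaN; callers decide
    whether to exclude or fail (the ranking screen excludes them).
    """
    values = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)
    if values.shape[1] < 4:
        raise ValueError(f"kurtosis needs at least 4 samples, got {values.shape[1]}")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant genes trigger scipy's precision warning; they are masked below
        warnings.simplefilter("ignore", RuntimeWarning)
        k = stats.kurtosis(values, axis=1, fisher=False, bias=True)
    k = np.asarray(k, dtype=float)
    k[values.var(axis=1) == 0.0] = np.nan
    return k


def rank_bimodal(x: ExpressionMatrix, top_n: int = 10) -> BimodalityReport:
    """Rank genes by ascending kurtosis (most bimodal first).

    Ties are broken lexicographically by gene id. ``top_n`` larger than the
    number of screened genes is truncated with a warning.
    """
    kurt = gene_kurtosis(x)
    screened = ~np.isnan(kurt)
    excluded = [g for g, ok in zip(x.gene_ids, screened) if not ok]
    genes = np.array(x.gene_ids, dtype=object)[screened]
    values = kurt[screened]
    order = np.lexsort((genes, values))  # primary: kurtosis, secondary: gene id
    table = pd.DataFrame(
        {"kurtosis": values[order], "rank": np.arange(1, len(order) + 1)},
        index=pd.Index(genes[order], name="gene_id"),
    )
    if top_n > len(table):
        warnings.warn(
            f"top_n={top_n} exceeds the {len(table)} screened genes; truncating",
            stacklevel=2,
        )
        top_n = len(table)
    return BimodalityReport(table=table, excluded=excluded, top_n=top_n)


def split_by_gene(x: ExpressionMatrix, gene_id: str) -> np.ndarray:
    """Binary sample partition from 1-D 2-means on one gene's expression.

    Centers are initialised at the minimum and maximum value (deterministic;
    no seed dependence), Lloyd iterations run to convergence, and the cluster
    with the smaller mean is labelled 0. Raises for a constant gene.
    """
    row = x.values[x.gene_index([gene_id])[0]]
    lo, hi = float(row.min()), float(row.max())
    if lo == hi:
        raise ValueError(f"gene {gene_id!r} is constant; no split exists")
    centers = np.array([lo, hi])
    labels = np.zeros(row.shape[0], dtype=int)
    for _ in range(200):
        new_labels = (np.abs(row - centers[1]) < np.abs(row - centers[0])).astype(int)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for c in (0, 1):
            if np.any(labels == c):
                centers[c] = row[labels == c].mean()
    if centers[0] > centers[1]:
        labels = 1 - labels
    return labels
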