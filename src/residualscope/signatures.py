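"""Group signatures and inter-/intra-group correlation structure.

A group *signature* is the vector pointing from the overall dataset mean to
the group's mean expression. Computed on the residual matrix (whose overall
mean is zero by construction) it becomes the residual group mean. Comparing
signature correlation matrices before and after the projected/residual split
shows how much inter-group correlation the leading components carry, while
within-group sample correlations show how much group-specific coherence the
residual retains.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_io import ExpressionMatrix, SampleAnnotation

__all__ = [
    "SignatureSet",
    "group_signatures",
    "signature_correlation",
    "within_group_correlation",
]


@dataclass
class SignatureSet:
    """Genes x groups matrix of mean-referenced group signatures."""

    vectors: np.ndarray
    group_labels: list[str]
    group_sizes: list[int]
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[1] != len(self.group_labels):
            raise ValueError("one column per group label required")
        if len(set(self.group_labels)) != len(self.group_labels):
            raise ValueError("group labels must be unique")

    def to_frame(self) -> pd.DataFrame:
        idx = self.gene_ids if self.gene_ids is not None else range(self.vectors.shape[0])
        return pd.DataFrame(self.vectors, index=pd.Index(idx, name="gene_id"),
                            columns=self.group_labels)


def group_signatures(
    x: ExpressionMatrix,
    annotation: SampleAnnotation,
    min_group_size: int = 10,
    by: str = "group",
) -> SignatureSet:
    """One signature column (group mean minus overall mean) per qualifying group.

    On a residual matrix the overall mean is ~0, so columns reduce to the
    residual group means. Groups are ordered lexicographically.
    """
    in_x = set(x.sample_ids)
    members = {
        g: [s for s in annotation.members(g, by=by) if s in in_x]
        for g in annotation.table[by].unique()
    }
    labels = sorted(g for g, m in members.items() if len(m) >= min_group_size)
    if not labels:
        raise ValueError(f"no group with at least {min_group_size} samples")
    overall = x.values.mean(axis=1)
    cols = np.empty((x.n_genes, len(labels)))
    sizes = []
    for j, g in enumerate(labels):
        idx = x.sample_index(members[g])
        cols[:, j] = x.values[:, idx].mean(axis=1) - overall
        sizes.append(len(idx))
    return SignatureSet(cols, labels, sizes, gene_ids=list(x.gene_ids))


def signature_correlation(s: SignatureSet) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlations between signatures plus a dendrogram leaf order.

    Returns the labelled symmetric correlation matrix (in the signature set's
    own label order) and the leaf order from complete-linkage hierarchical
    clustering of the signature columns under euclidean distance. SciPy's
    linkage breaks distance ties by original index, so the order is
    deterministic.
    """
    if len(s.group_labels) < 2:
        raise ValueError("need at least 2 signatures")
    sd = s.vectors.std(axis=0)
    for j, label in enumerate(s.group_labels):
        if sd[j] == 0.0:
            raise ValueError(f"constant signature for group {label!r}")
    corr = np.corrcoef(s.vectors.T)
    corr_df = pd.DataFrame(corr, index=s.group_labels, columns=s.group_labels)
    link = hierarchy.linkage(pdist(s.vectors.T, metric="euclidean"), method="complete")
    order = [s.group_labels[i] for i in hierarchy.leaves_list(link)]
    return corr_df, order


def _mean_pairwise_correlation(cols: np.ndarray) -> float:
    """Mean Pearson correlation over all unordered column pairs."""
    n = cols.shape[1]
    centered = cols - cols.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    vals = []
    for i, j in combinations(range(n), 2):
        denom = norms[i] * norms[j]
        vals.append(float(centered[:, i] @ centered[:, j] / denom) if denom > 0 else 0.0)
    return float(np.mean(vals))


def within_group_correlation(
    x: ExpressionMatrix,
    annotation: SampleAnnotation,
    min_group_size: int = 10,
    by: str = "group",
    center: bool = True,
) -> pd.DataFrame:
    """Per-group mean pairwise Pearson correlation between member samples.

    With ``center=True`` (original-space convention) the overall per-gene
    dataset mean is subtracted from every sample first, making the statistic
    comparable to the residual-space version, where the data are used as-is
    (``center=False``) because the residual is already mean-free.
    """
    in_x = set(x.sample_ids)
    members = {
        g: [s for s in annotation.members(g, by=by) if s in in_x]
        for g in annotation.table[by].unique()
    }
    labels = sorted(g for g, m in members.items() if len(m) >= min_group_size)
    if not labels:
        raise ValueError(f"no group with at least {min_group_size} samples")
    values = x.values - x.values.mean(axis=1, keepdims=True) if center else x.values
    rows = []
    for g in labels:
        idx = x.sample_index(members[g])
        rows.append((g, len(idx), _mean_pairwise_correlation(values[:, idx])))
    return pd.DataFrame(rows, columns=["group", "n", "mean_r"]).set_index("group")
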