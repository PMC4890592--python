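"""Projection of samples onto predefined, biologically annotated directions.

Instead of letting PCA choose the axes, a fixed set of annotated directions
(e.g. tissue-specific expression patterns derived from a reference
compendium) is supplied, and every sample's deviation from the dataset mean
is projected onto each unit direction by a scalar product. This surfaces
groups that PCA misses when they hold too few samples, and scores samples on
interpretable axes — including flagging samples whose score on their own
annotated direction is suspiciously low (likely mislabels).

This is a plain linear variant of direction-space scoring; rank-based
variants exist but are out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, SampleAnnotation

__all__ = ["DirectionSet", "load_directions", "score_samples", "flag_outlier_annotations"]


@dataclass
class DirectionSet:
    """Genes x directions matrix with unit-norm columns and unique labels."""

    vectors: np.ndarray
    direction_labels: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if len(set(self.direction_labels)) != len(self.direction_labels):
            raise ValueError("direction labels must be unique")
        norms = np.linalg.norm(self.vectors, axis=0)
        for j, label in enumerate(self.direction_labels):
            if norms[j] == 0.0:
                raise ValueError(f"direction {label!r} has zero norm")
        self.vectors = self.vectors / norms

    @property
    def n_directions(self) -> int:
        return self.vectors.shape[1]


def load_directions(path: str | Path) -> DirectionSet:
    """Read a genes x directions TSV and unit-normalise every column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-finite value in direction file {path}")
    return DirectionSet(values, [str(c) for c in df.columns], [str(g) for g in df.index])


def score_samples(x: ExpressionMatrix, d: DirectionSet) -> pd.DataFrame:
    """Scalar products of mean-centered sample deviations with each direction.

    Restricted to the genes common to the matrix and the direction set (in
    the matrix's row order); directions are re-normalised on that common set
    so scores remain comparable across direction sets with different
    coverage. A sample equal to the dataset mean scores 0 everywhere.
    """
    dir_rows = {g: i for i, g in enumerate(d.gene_ids)}
    common = [g for g in x.gene_ids if g in dir_rows]
    if not common:
        raise ValueError("empty gene intersection between matrix and directions")
    xi = x.gene_index(common)
    di = np.array([dir_rows[g] for g in common])
    vec = d.vectors[di, :]
    norms = np.linalg.norm(vec, axis=0)
    for j, label in enumerate(d.direction_labels):
        if norms[j] == 0.0:
            raise ValueError(f"direction {label!r} vanishes on the common gene set")
    vec = vec / norms
    sub = x.values[xi, :]
    dev = sub - sub.mean(axis=1, keepdims=True)
    return pd.DataFrame(dev.T @ vec, index=x.sample_ids, columns=d.direction_labels)


def flag_outlier_annotations(
    scores: pd.DataFrame,
    annotation: SampleAnnotation,
    label: str,
    score_label: str,
    z_threshold: float = 3.0,
    by: str = "group",
) -> list[str]:
    """Samples annotated as ``label`` whose ``score_label`` score is robustly low.

    A sample is flagged when its score lies more than ``z_threshold`` robust
    z-units (median / scaled MAD) *below* the label's median score — a
    mislabel signature. With ``z_threshold=0`` everything strictly below the
    median is flagged (degenerate but well-defined). Requires at least three
    annotated samples present in the score table.
    """
    if score_label not in scores.columns:
        raise KeyError(f"no direction {score_label!r} in the score table")
    members = [s for s in annotation.members(label, by=by) if s in scores.index]
    if len(members) < 3:
        raise ValueError(f"fewer than 3 samples annotated {label!r} have scores")
    vals = scores.loc[members, score_label].to_numpy(dtype=float)
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med))) * 1.4826
    flagged = [s for s, v in zip(members, vals) if med - v > z_threshold * mad]
    return flagged
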