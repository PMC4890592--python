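"""Residual-subset PCA, proportion-matched downsampling and sample-size scans.

PCA on the *full* residual matrix would only recover components k+1, k+2, …
of the parent model. PCA on the residual restricted to a sample *subset*,
however, can reveal directions that were invisible in the full dataset
because too few samples carried them — the subset raises the fraction of
samples with the signal and hence its share of the variance. The companion
operations quantify the other side of the same coin: how the visibility of a
minority group's direction in the leading components depends on how many of
its samples are present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, SampleAnnotation
from .decomposition import PCAModel, fit_pca

__all__ = [
    "SubsetPCAResult",
    "SampleSizeScan",
    "residual_subset_pca",
    "validate_on_external",
    "downsample_to_proportions",
    "sample_size_scan",
]


@dataclass
class SubsetPCAResult:
    """PCA refitted on the residual submatrix of a sample subset."""

    subset_sample_ids: list[str]
    residual_model: PCAModel
    parent_k: int


@dataclass
class SampleSizeScan:
    """Alignment of the target group with the leading PCs along a fraction grid."""

    fractions: list[float]
    alignment: list[float]
    aligned_pc_index: list[int]
    target_group: str
    n_top_pcs: int
    seed: int
    n_target: list[int] = field(default_factory=list)
    direction_cosine: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "fraction": self.fractions,
            "n_target": self.n_target,
            "alignment": self.alignment,
            "aligned_pc": self.aligned_pc_index,
        }
        if self.direction_cosine:
            data["direction_cosine"] = self.direction_cosine
        return pd.DataFrame(data)


def residual_subset_pca(
    residual: ExpressionMatrix,
    subset: Sequence[str],
    m: int,
    parent_k: int = 0,
) -> SubsetPCAResult:
    """Fit ``m`` components on the residual columns of a sample subset.

    Genes are re-centered within the subset: the residual has zero overall
    mean but not zero subset mean. With ``subset`` equal to all samples this
    reproduces the parent components k+1 … k+m (orthogonal-complement
    identity); the interesting use is a proper subset, where new directions
    can surface.
    """
    subset = list(subset)
    if len(subset) < m + 1:
        raise ValueError(f"subset of {len(subset)} samples too small for m={m} components")
    sub = residual.subset_samples(subset)
    model = fit_pca(sub, m)
    return SubsetPCAResult(subset_sample_ids=subset, residual_model=model, parent_k=parent_k)


def validate_on_external(
    x_val: ExpressionMatrix,
    parent_loadings: np.ndarray,
    subset_model: SubsetPCAResult,
) -> np.ndarray:
    """Project an independent cohort onto previously found residual-subset PCs.

    The validation samples are centered by their *own* gene means, the
    parent-k projection is subtracted, and the remaining residual is pushed
    onto the subset model's loadings by scalar products. Gene spaces must be
    aligned beforehand (``map_genes``). Returns a samples x m score matrix.
    """
    parent_loadings = np.asarray(parent_loadings, dtype=float)
    if parent_loadings.ndim != 2 or parent_loadings.shape[0] != x_val.n_genes:
        raise ValueError("parent loadings not aligned with validation gene space")
    sub_loadings = subset_model.residual_model.loadings
    if sub_loadings.shape[0] != x_val.n_genes:
        raise ValueError("subset model not aligned with validation gene space")
    if x_val.n_genes == 0:
        raise ValueError("empty gene intersection")
    xc = x_val.values - x_val.values.mean(axis=1, keepdims=True)
    residual = xc - parent_loadings @ (parent_loadings.T @ xc)
    return residual.T @ sub_loadings


def downsample_to_proportions(
    annotation: SampleAnnotation,
    target_counts: Mapping[str, int],
    keep_all: Sequence[str] = (),
    seed: int = 0,
    by: str = "large_scale_group",
) -> list[str]:
    """Simple random subsample with exact per-group counts, keeping some groups whole.

    Samples are sorted by id before drawing so the result depends only on the
    seed and the requested counts, not on annotation row order.
    """
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for label in sorted(keep_all):
        members = sorted(annotation.members(label, by=by))
        if not members:
            raise ValueError(f"group {label!r} has no samples")
        chosen.extend(members)
    for label in sorted(target_counts):
        count = int(target_counts[label])
        members = sorted(annotation.members(label, by=by))
        if count > len(members):
            raise ValueError(
                f"requested {count} samples from group {label!r} "
                f"but only {len(members)} are available"
            )
        if count > 0:
            chosen.extend(rng.choice(members, size=count, replace=False).tolist())
    return sorted(chosen)


def _point_biserial(scores: np.ndarray, indicator: np.ndarray) -> float:
    """|Pearson correlation| between one PC's scores and a binary indicator."""
    if indicator.std() == 0.0 or scores.std() == 0.0:
        return 0.0
    return float(abs(np.corrcoef(scores, indicator)[0, 1]))


def sample_size_scan(
    x: ExpressionMatrix,
    annotation: SampleAnnotation,
    target_group: str,
    fractions: Sequence[float],
    n_top_pcs: int = 4,
    seed: int = 0,
    by: str = "group",
    reference_direction: np.ndarray | None = None,
) -> SampleSizeScan:
    """Refit PCA while varying how many target-group samples are included.

    For each fraction f all non-target samples are kept and a seeded random
    ceil(f * n_target) subset of the target group is added. Alignment is the
    maximum |point-biserial correlation| between any of the first
    ``n_top_pcs`` score vectors and the target indicator; a constant
    indicator (target group = everything) yields alignment 0 by convention.
    If ``reference_direction`` is given (e.g. the generator's ground-truth
    minority direction), the maximum |cosine| between it and the top
    loadings is recorded as well.
    """
    in_x = set(x.sample_ids)
    target = sorted(s for s in annotation.members(target_group, by=by) if s in in_x)
    if not target:
        raise ValueError(f"target group {target_group!r} is empty")
    others = sorted(s for s in x.sample_ids if s not in set(target))
    if reference_direction is not None:
        ref = np.asarray(reference_direction, dtype=float).ravel()
        ref = ref / np.linalg.norm(ref)

    result = SampleSizeScan(
        fractions=[], alignment=[], aligned_pc_index=[],
        target_group=target_group, n_top_pcs=n_top_pcs, seed=seed,
    )
    for i, f in enumerate(fractions):
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fractions must lie in (0, 1]; got {f}")
        n_keep = math.ceil(f * len(target))
        if n_keep == 0:
            raise ValueError(f"fraction {f} keeps zero target samples")
        rng = np.random.default_rng([seed, i])
        kept = sorted(rng.choice(target, size=n_keep, replace=False).tolist())
        subset_ids = others + kept
        sub = x.subset_samples(subset_ids)
        model = fit_pca(sub, n_top_pcs)
        indicator = np.array([1.0 if s in set(kept) else 0.0 for s in subset_ids])
        pbs = [_point_biserial(model.scores[:, j], indicator) for j in range(n_top_pcs)]
        best = int(np.argmax(pbs))
        result.fractions.append(float(f))
        result.n_target.append(n_keep)
        result.alignment.append(pbs[best])
        result.aligned_pc_index.append(best + 1)
        if reference_direction is not None:
            cosines = np.abs(model.loadings.T @ ref)
            result.direction_cosine.append(float(cosines.max()))
    return result
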