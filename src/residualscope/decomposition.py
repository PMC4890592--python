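"""PCA fitting and exact projected/residual decomposition of expression matrices.

Samples are the observations and genes the variables: each gene is centered by
its mean across samples, with no variance scaling (the convention for
log-scale RMA data). The fit goes through a singular value decomposition of
the centered genes x samples matrix, which is numerically stable in the usual
regime of many more genes than samples.

For a centered matrix ``Xc`` and the first ``k`` loading columns ``L`` the
*projected* matrix is ``L (L^T Xc)`` — the reconstruction from the first k
components — and the *residual* matrix is ``Xc`` minus that reconstruction,
housing components k+1 and higher. Both have the full size of the input, so
any per-gene statistic can be computed in either subspace and compared.

Sign convention: every loading column is flipped so that its
largest-magnitude entry is positive (ties broken by the first index). PC
signs are mathematically arbitrary; fixing them makes results reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix

__all__ = ["PCAModel", "Decomposition", "fit_pca", "decompose", "project_external", "loading_r2"]

#: relative tolerance for the reconstruction/orthogonality identities
RECONSTRUCTION_TOL = 1e-8


@dataclass
class PCAModel:
    """A fitted PCA: per-gene center, loadings, scores and variance fractions.

    ``loadings`` is genes x k with orthonormal columns; ``scores`` is
    samples x k with ``scores = centered_data^T @ loadings``.
    ``explained_fraction[j]`` is eigenvalue_j over the *total* centered
    variance, so the k reported fractions need not sum to one.
    """

    center: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    explained_fraction: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    total_variance: float = 0.0

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def save(self, prefix: str | Path) -> None:
        """Write center, loadings, scores and variance fractions as TSV."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        pcs = [f"PC{j + 1}" for j in range(self.n_components)]
        pd.DataFrame(self.loadings, index=self.gene_ids, columns=pcs).rename_axis(
            "gene_id"
        ).to_csv(f"{prefix}.loadings.tsv", sep="\t")
        pd.DataFrame(self.scores, index=self.sample_ids, columns=pcs).rename_axis(
            "sample_id"
        ).to_csv(f"{prefix}.scores.tsv", sep="\t")
        pd.Series(self.center, index=self.gene_ids, name="center").rename_axis(
            "gene_id"
        ).to_csv(f"{prefix}.center.tsv", sep="\t")
        pd.Series(self.explained_fraction, index=pcs, name="explained_fraction").rename_axis(
            "component"
        ).to_csv(f"{prefix}.explained.tsv", sep="\t")


@dataclass
class Decomposition:
    """Projected and residual matrices for a chosen number of components k."""

    projected: np.ndarray
    residual: np.ndarray
    k: int
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def projected_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix(self.projected, list(self.gene_ids), list(self.sample_ids))

    def residual_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix(self.residual, list(self.gene_ids), list(self.sample_ids))


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0


def fit_pca(x: ExpressionMatrix, k: int) -> PCAModel:
    """Fit a gene-centered, unscaled PCA and retain the first ``k`` components.

    Raises if ``k`` is outside ``[1, min(n_samples - 1, n_genes)]`` (centering
    removes one sample degree of freedom) or if the matrix has zero variance.
    """
    n_genes, n_samples = x.values.shape
    k_max = min(n_samples - 1, n_genes)
    if not 1 <= k <= k_max:
        raise ValueError(f"k={k} out of range [1, {k_max}] for {n_genes} genes x {n_samples} samples")
    center = x.values.mean(axis=1)
    xc = x.values - center[:, None]
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = s**2 / (n_samples - 1)
    total = float(eigvals.sum())
    if total <= 0.0:
        raise ValueError("constant matrix: total centered variance is zero")
    loadings = u[:, :k].copy()
    scores = (vt[:k].T * s[:k]).copy()
    _fix_signs(loadings, scores)
    return PCAModel(
        center=center,
        loadings=loadings,
        scores=scores,
        explained_fraction=eigvals[:k] / total,
        gene_ids=list(x.gene_ids),
        sample_ids=list(x.sample_ids),
        total_variance=total,
    )


def decompose(x: ExpressionMatrix, model: PCAModel, k: int) -> Decomposition:
    """Split centered ``x`` into rank-k projected and residual matrices.

    ``k = 0`` yields an all-zero projected matrix (the residual is the full
    centered data); ``projected + residual`` equals the centered input exactly.
    """
    if not 0 <= k <= model.n_components:
        raise ValueError(f"k={k} exceeds the {model.n_components} fitted components")
    if list(x.gene_ids) != list(model.gene_ids):
        raise ValueError("gene set of matrix does not match the fitted model")
    xc = x.values - model.center[:, None]
    if k == 0:
        projected = np.zeros_like(xc)
    else:
        lk = model.loadings[:, :k]
        projected = lk @ (lk.T @ xc)
    return Decomposition(
        projected=projected,
        residual=xc - projected,
        k=k,
        gene_ids=list(x.gene_ids),
        sample_ids=list(x.sample_ids),
    )


def project_external(x_new: ExpressionMatrix, foreign_loadings: np.ndarray) -> np.ndarray:
    """Project a dataset onto loadings fitted elsewhere (cross-dataset scores).

    Gene spaces must already be intersected and row-aligned (see
    :func:`residualscope.core_io.map_genes`). Centering uses ``x_new``'s own
    per-gene means, so the foreign model's center is never needed.
    """
    foreign_loadings = np.asarray(foreign_loadings, dtype=float)
    if foreign_loadings.ndim != 2 or foreign_loadings.shape[0] != x_new.n_genes:
        raise ValueError(
            f"loadings have {foreign_loadings.shape[0]} gene rows, "
            f"matrix has {x_new.n_genes}; align gene sets first"
        )
    if foreign_loadings.shape[0] == 0:
        raise ValueError("empty gene intersection")
    xc = x_new.values - x_new.values.mean(axis=1, keepdims=True)
    return xc.T @ foreign_loadings


def loading_r2(target: np.ndarray, predictors: np.ndarray) -> float:
    """OLS R-squared of a gene-space vector regressed on loading columns.

    Used to quantify how well one PCA model's component is represented in the
    span of another model's components (plus an intercept). Invariant to any
    invertible recombination of the predictor columns.
    """
    target = np.asarray(target, dtype=float).ravel()
    predictors = np.asarray(predictors, dtype=float)
    if predictors.ndim == 1:
        predictors = predictors[:, None]
    n, m = predictors.shape
    if target.shape[0] != n:
        raise ValueError("target and predictors must share the gene axis")
    if n < m + 1:
        raise ValueError(f"underdetermined: {n} genes for {m} predictors plus intercept")
    design = np.column_stack([np.ones(n), predictors])
    beta, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ beta
    ss_tot = float(np.sum((target - target.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant target vector: R^2 undefined")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    # clamp tiny numerical excursions outside [0, 1]
    return min(1.0, max(0.0, r2))
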