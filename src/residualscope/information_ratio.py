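"""The information-ratio (IR) statistic: where does two-group evidence live?

For a contrast between two sample groups, per-gene two-sample p-values are
computed three times — on the original data, on the projected matrix (first k
PCs) and on the residual matrix (components k+1 and higher). Summing
``-log10 p`` over genes within each subspace gives evidence totals ``S_P``
and ``S_R``; the information ratio

    IR = S_R / (S_P + S_R)

lies in [0, 1]: low values mean the contrast is captured by the leading
components, high values mean it survives almost entirely in the residual
space. By convention IR = 0.5 when both totals vanish (no signal anywhere).

The per-gene test defaults to Welch's unequal-variance t-test, the safer
choice for heterogeneous compendia; a pooled-variance option is provided.
Genes constant in both groups carry no information and contribute p = 1.
P-values are floored at 1e-300 so the log transform stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, SampleAnnotation
from .decomposition import PCAModel, decompose

__all__ = [
    "IRResult",
    "group_pvalues",
    "information_ratio",
    "ir_for_groups",
    "ir_dimension_scan",
    "pairwise_ir_matrix",
]

P_FLOOR = 1e-300


@dataclass
class IRResult:
    """Per-gene p-values in the three spaces plus the scalar IR for one contrast.

    ``log10_p_*`` properties expose the scatter coordinates of subspace
    p-values against original-space p-values.
    """

    p_original: np.ndarray
    p_projected: np.ndarray
    p_residual: np.ndarray
    ir: float
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    k: int = 0
    gene_ids: list[str] | None = None

    @property
    def log10_p_original(self) -> np.ndarray:
        return np.log10(self.p_original)

    @property
    def log10_p_projected(self) -> np.ndarray:
        return np.log10(self.p_projected)

    @property
    def log10_p_residual(self) -> np.ndarray:
        return np.log10(self.p_residual)

    def to_frame(self) -> pd.DataFrame:
        idx = self.gene_ids if self.gene_ids is not None else range(len(self.p_original))
        return pd.DataFrame(
            {
                "p_original": self.p_original,
                "p_projected": self.p_projected,
                "p_residual": self.p_residual,
            },
            index=pd.Index(idx, name="gene_id"),
        )


def _two_sample_pvalues(a: np.ndarray, b: np.ndarray, test: str) -> np.ndarray:
    """Vectorised two-sample t-test p-values per gene (rows).

    Handles the degenerate zero-variance cases explicitly: equal means give
    p = 1 (no information), unequal means with zero variance give the floor.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    diff = ma - mb
    if test == "welch":
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    elif test == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = np.full(a.shape[0], na + nb - 2, dtype=float)
    else:
        raise ValueError(f"unknown test {test!r}; use 'welch' or 'pooled'")

    p = np.ones(a.shape[0])
    # a standard error at double-precision dust level is a numerical zero
    # (e.g. the residual matrix at full rank); equal means then carry no
    # information (p = 1) while distinct means saturate at the floor
    degenerate = se2 <= 1e-24
    exact_zero = degenerate & (np.abs(diff) <= 1e-12)
    forced = degenerate & ~exact_zero
    ok = ~degenerate
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(diff[ok]) / np.sqrt(se2[ok])
    p[ok] = 2.0 * stats.t.sf(t, df[ok])
    p[exact_zero] = 1.0
    p[forced] = P_FLOOR
    return np.maximum(p, P_FLOOR)


def group_pvalues(
    x: np.ndarray | ExpressionMatrix,
    members_a: Sequence[int] | Sequence[str],
    members_b: Sequence[int] | Sequence[str],
    test: str = "welch",
) -> np.ndarray:
    """Per-gene two-sample p-values between two disjoint sample sets.

    ``x`` may be a raw genes x samples array (members given as column
    indices) or an :class:`ExpressionMatrix` (members given as sample ids).
    Each group needs at least two samples.
    """
    if isinstance(x, ExpressionMatrix):
        idx_a = x.sample_index(members_a)
        idx_b = x.sample_index(members_b)
        values = x.values
    else:
        values = np.asarray(x, dtype=float)
        idx_a = np.asarray(members_a, dtype=int)
        idx_b = np.asarray(members_b, dtype=int)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if set(idx_a.tolist()) & set(idx_b.tolist()):
        raise ValueError("groups must be disjoint")
    return _two_sample_pvalues(values[:, idx_a], values[:, idx_b], test)


def information_ratio(p_projected: np.ndarray, p_residual: np.ndarray) -> float:
    """IR = S_R / (S_P + S_R) with S = sum over genes of -log10 p."""
    p_projected = np.asarray(p_projected, dtype=float)
    p_residual = np.asarray(p_residual, dtype=float)
    if p_projected.shape != p_residual.shape:
        raise ValueError("p-value vectors must have equal length")
    s_p = float(-np.log10(np.maximum(p_projected, P_FLOOR)).sum())
    s_r = float(-np.log10(np.maximum(p_residual, P_FLOOR)).sum())
    if s_p + s_r == 0.0:
        return 0.5
    return s_r / (s_p + s_r)


def _resolve_groups(
    x: ExpressionMatrix, annotation: SampleAnnotation, label: str, by: str
) -> list[str]:
    members = [s for s in annotation.members(label, by=by) if s in set(x.sample_ids)]
    if not members:
        raise KeyError(f"unknown or empty group label {label!r}")
    return members


def ir_for_groups(
    x: ExpressionMatrix,
    model: PCAModel,
    k: int,
    annotation: SampleAnnotation,
    group_a: str,
    group_b: str,
    by: str = "group",
    test: str = "welch",
) -> IRResult:
    """Decompose at ``k`` and compute original/projected/residual p-values + IR."""
    members_a = _resolve_groups(x, annotation, group_a, by)
    members_b = _resolve_groups(x, annotation, group_b, by)
    dec = decompose(x, model, k)
    idx_a = x.sample_index(members_a)
    idx_b = x.sample_index(members_b)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    p_orig = _two_sample_pvalues(x.values[:, idx_a], x.values[:, idx_b], test)
    p_proj = _two_sample_pvalues(dec.projected[:, idx_a], dec.projected[:, idx_b], test)
    p_res = _two_sample_pvalues(dec.residual[:, idx_a], dec.residual[:, idx_b], test)
    return IRResult(
        p_original=p_orig,
        p_projected=p_proj,
        p_residual=p_res,
        ir=information_ratio(p_proj, p_res),
        group_a=group_a,
        group_b=group_b,
        n_a=len(idx_a),
        n_b=len(idx_b),
        k=k,
        gene_ids=list(x.gene_ids),
    )


def ir_dimension_scan(
    x: ExpressionMatrix,
    model: PCAModel,
    annotation: SampleAnnotation,
    group_a: str,
    group_b: str,
    k_values: Sequence[int],
    by: str = "group",
    test: str = "welch",
) -> list[tuple[int, float]]:
    """IR as a function of the number of projected dimensions k.

    The k at which the IR drops localises the components carrying the
    contrast (e.g. a sex signal sitting in intermediate PCs).
    """
    out = []
    for k in k_values:
        res = ir_for_groups(x, model, k, annotation, group_a, group_b, by=by, test=test)
        out.append((int(k), res.ir))
    return out


def pairwise_ir_matrix(
    x: ExpressionMatrix,
    model: PCAModel,
    k: int,
    annotation: SampleAnnotation,
    min_group_size: int = 10,
    by: str = "group",
    test: str = "welch",
) -> pd.DataFrame:
    """Symmetric IR matrix over all group pairs passing the size filter.

    The diagonal is NaN (a group against itself is undefined).
    """
    in_x = set(x.sample_ids)
    sizes = {
        g: [s for s in annotation.members(g, by=by) if s in in_x]
        for g in annotation.table[by].unique()
    }
    labels = sorted(g for g, m in sizes.items() if len(m) >= min_group_size)
    if len(labels) < 2:
        raise ValueError(f"fewer than 2 groups with at least {min_group_size} samples")
    dec = decompose(x, model, k)
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        ia = x.sample_index(sizes[a])
        ib = x.sample_index(sizes[b])
        p_proj = _two_sample_pvalues(dec.projected[:, ia], dec.projected[:, ib], test)
        p_res = _two_sample_pvalues(dec.residual[:, ia], dec.residual[:, ib], test)
        ir = information_ratio(p_proj, p_res)
        out.loc[a, b] = ir
        out.loc[b, a] = ir
    return out
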