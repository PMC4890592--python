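"""Ground-truth generator for compendium-like expression matrices.

The generator emulates the statistical structure that large heterogeneous
microarray compendia exhibit on log2 scale:

* a few *large-scale groups* (hematopoietic / brain / cell-line analogues)
  whose strong signatures dominate the leading principal components;
* *subtypes* nested inside those groups, each with its own weaker signature
  (brain regions, cancer types) that lives beyond the first components;
* a *minority group* (liver analogue) holding a small, tunable fraction of
  samples — the sample-size failure mode of PCA;
* a *genetic* few-gene signal (sex analogue): a large per-gene shift on a
  handful of genes for a carrier subset, with small overall effect size —
  the effect-size failure mode of PCA;
* per-study batch offsets and i.i.d. Gaussian measurement noise.

The generative model for gene g, sample s is

    x[g, s] = mu[g]
              + delta_L * u_L[g]                (large-scale group of s)
              + delta_c * u_c[g]                (fine group of s)
              + delta_m * w[g]                  (if s in the minority group)
              + d * 1[g in genetic set]         (if s is a carrier)
              + beta[study(s), g]               (batch)
              + eps[g, s]                       (noise)

with mu ~ N(baseline_mean, baseline_sd^2); u, w unit-norm sparse direction
vectors drawn once per seed (so delta is the total log2 effect energy and
sparsity sets how many genes carry it); beta ~ N(0, batch_sd^2);
eps ~ N(0, noise_sd^2). With ``effect_continuum`` the per-gene magnitudes on
a direction's support are exponential, giving the continuum of differential
expression typical of non-genetic contrasts; otherwise they are equal.

Everything is reproducible from the config seed. ``generate(config,
cohort_seed=...)`` redraws samples, batches and noise while keeping the
direction vectors and gene set fixed — an independent validation cohort
measuring the same underlying biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, SampleAnnotation

__all__ = [
    "GroupSpec",
    "MinoritySpec",
    "GeneticSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate",
    "preset",
    "PRESET_NAMES",
    "LIVER_SCAN_FRACTIONS",
]

#: default fraction grid for the liver-analogue sample-size scan
LIVER_SCAN_FRACTIONS = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass(frozen=True)
class GroupSpec:
    """A fine sample group: label, parent large-scale group, size and effect."""

    label: str
    large_scale_group: str
    n_samples: int
    effect_size: float = 0.0  # total log2 energy of the group-specific direction
    sparsity: float = 0.1  # fraction of genes carrying the direction


@dataclass(frozen=True)
class MinoritySpec:
    """A minority group occupying a tunable fraction of all samples."""

    label: str
    fraction: float
    effect_size: float
    sparsity: float = 0.1
    large_scale_group: str = "other"


@dataclass(frozen=True)
class GeneticSpec:
    """Few-gene, large-per-gene-effect carrier signal (sex analogue)."""

    n_genes: int
    shift: float  # log2 shift added to carriers on every affected gene
    carrier_fraction: float


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int
    groups: tuple[GroupSpec, ...]
    large_scale_effects: Mapping[str, float] = field(default_factory=dict)
    large_scale_sparsity: float = 0.1
    minority: Optional[MinoritySpec] = None
    genetic: Optional[GeneticSpec] = None
    effect_continuum: bool = True
    n_studies: int = 1
    batch_sd: float = 0.0
    noise_sd: float = 0.25
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if any(g.n_samples < 0 for g in self.groups):
            raise ValueError("group sizes must be non-negative")
        if self.minority is not None and not 0.0 < self.minority.fraction < 1.0:
            raise ValueError("minority fraction must lie in (0, 1)")
        if self.noise_sd < 0 or self.batch_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_studies < 1:
            raise ValueError("need at least one study")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated matrix, for parameter recovery."""

    annotation: SampleAnnotation
    group_directions: dict[str, np.ndarray]  # unit vectors, fine groups
    large_scale_directions: dict[str, np.ndarray]  # unit vectors
    effect_sizes: dict[str, float]  # fine-group label -> delta
    large_scale_effect_sizes: dict[str, float]
    minority_direction: Optional[np.ndarray]
    minority_label: Optional[str]
    genetic_gene_ids: list[str]
    carrier_mask: np.ndarray  # bool per sample
    study_of: np.ndarray  # study index per sample
    gene_effects: pd.DataFrame  # per-gene effect loadings, one column per direction

    def truth_frame(self) -> pd.DataFrame:
        """Per-sample ground-truth table (group, carrier status, study)."""
        t = self.annotation.table.copy()
        t["carrier"] = self.carrier_mask.astype(int)
        return t


def _unit_sparse(rng: np.random.Generator, n_genes: int, sparsity: float,
                 continuum: bool) -> np.ndarray:
    """Unit-norm direction supported on a random gene subset."""
    m = max(1, int(round(sparsity * n_genes)))
    idx = rng.choice(n_genes, size=m, replace=False)
    signs = rng.choice([-1.0, 1.0], size=m)
    mags = rng.standard_exponential(m) if continuum else np.ones(m)
    v = np.zeros(n_genes)
    v[idx] = signs * mags
    return v / np.linalg.norm(v)


def generate(
    config: SyntheticConfig, cohort_seed: Optional[int] = None
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one expression matrix plus its ground truth.

    ``cohort_seed`` redraws the sampling layer (sample-to-study assignment,
    carriers, batch offsets, noise) while keeping the structural layer
    (baselines, direction vectors, genetic gene set) fixed, yielding an
    independent cohort that shares the generating directions.
    """
    struct_rng = np.random.default_rng([config.seed, 0])
    sample_rng = np.random.default_rng(
        [config.seed if cohort_seed is None else cohort_seed, 1]
    )
    g = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(g)]

    # --- structural layer (shared across cohorts) ---
    mu = struct_rng.normal(config.baseline_mean, config.baseline_sd, size=g)
    ls_dirs = {
        label: _unit_sparse(struct_rng, g, config.large_scale_sparsity, config.effect_continuum)
        for label, eff in sorted(config.large_scale_effects.items())
        if eff > 0
    }
    fine_dirs = {
        spec.label: _unit_sparse(struct_rng, g, spec.sparsity, config.effect_continuum)
        for spec in config.groups
        if spec.effect_size > 0
    }
    # Subtype effects are deviations from their large-scale group's centroid:
    # within every large-scale group holding >= 2 effect-bearing fine groups,
    # the size-weighted mean effect is removed and each deviation is
    # renormalised to its configured energy. Without this, the centroid of a
    # group's subtypes leaks into the large-scale direction that dominates
    # the leading PCs, and projecting those out strips subtype signal too.
    by_ls: dict[str, list[GroupSpec]] = {}
    for spec in config.groups:
        by_ls.setdefault(spec.large_scale_group, []).append(spec)
    for specs in by_ls.values():
        bearing = [s for s in specs if s.label in fine_dirs]
        if len(bearing) < 2:
            continue
        n_ls = sum(s.n_samples for s in specs)
        mbar = sum(
            (s.n_samples / n_ls) * s.effect_size * fine_dirs[s.label] for s in bearing
        )
        for s in bearing:
            v = s.effect_size * fine_dirs[s.label] - mbar
            fine_dirs[s.label] = v / np.linalg.norm(v)
    minority_dir = None
    if config.minority is not None and config.minority.effect_size > 0:
        minority_dir = _unit_sparse(
            struct_rng, g, config.minority.sparsity, config.effect_continuum
        )
    genetic_idx = np.array([], dtype=int)
    if config.genetic is not None:
        if config.genetic.n_genes > g:
            raise ValueError("genetic signal requests more genes than exist")
        genetic_idx = np.sort(
            struct_rng.choice(g, size=config.genetic.n_genes, replace=False)
        )

    # --- sample layout ---
    labels: list[str] = []
    ls_labels: list[str] = []
    for spec in config.groups:
        labels.extend([spec.label] * spec.n_samples)
        ls_labels.extend([spec.large_scale_group] * spec.n_samples)
    n_base = len(labels)
    if config.minority is not None:
        f = config.minority.fraction
        n_min = int(round(f / (1.0 - f) * n_base))
        if n_min == 0:
            raise ValueError(
                f"minority fraction {f} yields zero samples for {n_base} base samples"
            )
        labels.extend([config.minority.label] * n_min)
        ls_labels.extend([config.minority.large_scale_group] * n_min)
    n = len(labels)
    if n == 0:
        raise ValueError("configuration yields zero samples")
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # --- sampling layer ---
    study_of = sample_rng.permutation(np.arange(n) % config.n_studies)
    carriers = np.zeros(n, dtype=bool)
    if config.genetic is not None:
        # Carrier status is apportioned within studies (largest-remainder
        # rounding to hit the exact total): real compendia have roughly
        # similar sex ratios across studies, and unstratified assignment
        # would confound the genetic contrast with batch structure.
        n_car = int(round(config.genetic.carrier_fraction * n))
        sizes = np.bincount(study_of, minlength=config.n_studies)
        quotas = config.genetic.carrier_fraction * sizes
        base = np.floor(quotas).astype(int)
        remainder = n_car - int(base.sum())
        order = np.argsort(-(quotas - base), kind="stable")
        per_study = base.copy()
        per_study[order[:remainder]] += 1
        for s in range(config.n_studies):
            members = np.flatnonzero(study_of == s)
            take = min(per_study[s], len(members))
            carriers[sample_rng.choice(members, size=take, replace=False)] = True
    batch = (
        sample_rng.normal(0.0, config.batch_sd, size=(config.n_studies, g))
        if config.batch_sd > 0
        else np.zeros((config.n_studies, g))
    )
    x = mu[:, None] + sample_rng.normal(0.0, config.noise_sd, size=(g, n))
    x += batch[study_of].T

    ls_effect = dict(config.large_scale_effects)
    for spec in config.groups:
        cols = [i for i, lab in enumerate(labels) if lab == spec.label]
        if not cols:
            continue
        shift = np.zeros(g)
        eff_l = ls_effect.get(spec.large_scale_group, 0.0)
        if eff_l > 0:
            shift += eff_l * ls_dirs[spec.large_scale_group]
        if spec.effect_size > 0:
            shift += spec.effect_size * fine_dirs[spec.label]
        x[:, cols] += shift[:, None]
    if config.minority is not None and minority_dir is not None:
        cols = [i for i, lab in enumerate(labels) if lab == config.minority.label]
        x[:, cols] += (config.minority.effect_size * minority_dir)[:, None]
    if config.genetic is not None and carriers.any():
        x[np.ix_(genetic_idx, np.flatnonzero(carriers))] += config.genetic.shift

    ann_table = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": labels,
            "large_scale_group": ls_labels,
            "sex": np.where(carriers, "M", "F") if config.genetic is not None else "",
            "study_id": [f"study{int(j):02d}" for j in study_of],
        }
    )
    annotation = SampleAnnotation(ann_table)

    effect_cols: dict[str, np.ndarray] = {}
    for lab, v in ls_dirs.items():
        effect_cols[f"ls:{lab}"] = ls_effect[lab] * v
    for spec in config.groups:
        if spec.label in fine_dirs:
            effect_cols[f"group:{spec.label}"] = spec.effect_size * fine_dirs[spec.label]
    if minority_dir is not None:
        effect_cols[f"minority:{config.minority.label}"] = (
            config.minority.effect_size * minority_dir
        )
    if config.genetic is not None:
        gvec = np.zeros(g)
        gvec[genetic_idx] = config.genetic.shift
        effect_cols["genetic"] = gvec
    gene_effects = pd.DataFrame(effect_cols, index=pd.Index(gene_ids, name="gene_id"))

    truth = SyntheticTruth(
        annotation=annotation,
        group_directions=fine_dirs,
        large_scale_directions=ls_dirs,
        effect_sizes={s.label: s.effect_size for s in config.groups if s.effect_size > 0},
        large_scale_effect_sizes={k: v for k, v in ls_effect.items() if v > 0},
        minority_direction=minority_dir,
        minority_label=config.minority.label if config.minority else None,
        genetic_gene_ids=[gene_ids[i] for i in genetic_idx],
        carrier_mask=carriers,
        study_of=study_of,
        gene_effects=gene_effects,
    )
    return ExpressionMatrix(x, gene_ids, sample_ids), truth


# ---------------------------------------------------------------------------
# Presets: the frozen study conditions used throughout the analyses and docs.
# Effect sizes are total log2 energies; with sparsity 0.1 on 2000 genes an
# energy of 21 corresponds to ~1.5 log2 units per carried gene. The staggered
# large-scale energies and the large unstructured background keep the three
# large-scale directions identifiable as individual leading components; the
# muscle/liver energies in liver_scan put the liver spike below the muscle
# spike at <=60% of the reference liver count and above it at 100%
# (spiked-covariance arithmetic in docs/methods.md).
# ---------------------------------------------------------------------------

def _compendium_config(seed: int, brain_regions: Sequence[str]) -> SyntheticConfig:
    nb = 68 // len(brain_regions) if len(brain_regions) == 4 else 17
    groups = [
        GroupSpec("t_cell", "hematopoietic", 20, 15.0),
        GroupSpec("b_cell", "hematopoietic", 20, 15.0),
        GroupSpec("myeloid", "hematopoietic", 20, 15.0),
        *[GroupSpec(r, "brain", nb, 15.0) for r in brain_regions],
        GroupSpec("cl_epithelial", "cell line", 14, 15.0),
        GroupSpec("cl_fibroblast", "cell line", 14, 15.0),
        GroupSpec("cl_leukemia", "cell line", 14, 15.0),
        GroupSpec("colorectal_cancer", "other", 25, 15.0),
        GroupSpec("ovarian_cancer", "other", 25, 15.0),
        GroupSpec("hepatocellular_carcinoma", "other", 25, 15.0),
    ]
    n_named = sum(s.n_samples for s in groups)
    groups.append(GroupSpec("misc", "other", 577 - n_named, 0.0))
    return SyntheticConfig(
        n_genes=2000,
        groups=tuple(groups),
        large_scale_effects={"hematopoietic": 34.0, "brain": 27.0, "cell line": 21.0},
        minority=MinoritySpec("liver", fraction=23 / 600, effect_size=9.0),
        genetic=GeneticSpec(n_genes=5, shift=4.0, carrier_fraction=0.5),
        n_studies=10,
        batch_sd=0.05,
        noise_sd=0.25,
        seed=seed,
    )


def preset(name: str) -> SyntheticConfig:
    """A fully specified, seed-embedded configuration for a named scenario.

    ``compendium``
        2000 genes x 600 samples: three large-scale groups with three
        subtypes each, three cancer subtypes in the unstructured background,
        a 3.8% liver-analogue minority and a 5-gene genetic signal.
    ``liver_scan``
        Same scale, no subtypes, plus a muscle-analogue competitor group
        calibrated so the liver direction enters the top 4 PCs only above
        ~70% of the reference liver sample count.
    ``sex_lymphoma``
        208 samples from one group (90/118 non-carrier/carrier split), an
        8-gene genetic signal of 4 log2 units per gene, and strong per-study
        batch structure — small overall effect size, huge per-gene effects.
    ``cancer_subset`` / ``brain_subset``
        Compendium variants (fresh seeds; four brain regions in
        ``brain_subset``) for residual-subset analyses.
    """
    if name == "compendium":
        return _compendium_config(1101, ("cerebellum", "frontal_cortex", "hypothalamus"))
    if name == "liver_scan":
        return SyntheticConfig(
            n_genes=2000,
            groups=(
                GroupSpec("hematopoietic", "hematopoietic", 120, 26.0),
                GroupSpec("brain", "brain", 100, 20.0),
                GroupSpec("cell_line", "cell line", 80, 15.0),
                GroupSpec("muscle", "muscle", 12, 8.7),
                GroupSpec("other", "other", 265, 0.0),
            ),
            minority=MinoritySpec("liver", fraction=23 / 600, effect_size=7.0),
            n_studies=10,
            batch_sd=0.05,
            noise_sd=0.2,
            seed=1102,
        )
    if name == "sex_lymphoma":
        return SyntheticConfig(
            n_genes=2000,
            groups=(GroupSpec("b_cell_lymphoma", "hematopoietic", 208, 0.0),),
            genetic=GeneticSpec(n_genes=8, shift=4.0, carrier_fraction=118 / 208),
            n_studies=8,
            batch_sd=0.5,
            noise_sd=0.25,
            seed=1103,
        )
    if name == "cancer_subset":
        return _compendium_config(1104, ("cerebellum", "frontal_cortex", "hypothalamus"))
    if name == "brain_subset":
        return _compendium_config(
            1105, ("caudate_nucleus", "hypothalamus", "frontal_cortex", "cerebellum")
        )
    raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")


PRESET_NAMES = ("compendium", "liver_scan", "sex_lymphoma", "cancer_subset", "brain_subset")
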