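# residualscope

How much biology do the first few principal components of a gene-expression
compendium actually capture — and what do they miss?

PCA on large heterogeneous microarray compendia (thousands of samples,
hundreds of tissues and cell types on log2/RMA scale) famously yields a
handful of interpretable leading components: hematopoietic vs the rest,
malignancy, neural tissue. It is tempting to conclude that expression space
is 3–4 dimensional. `residualscope` provides the tooling to test that
conclusion: it splits a dataset into the subspace spanned by the first *k*
principal components and everything beyond, and quantifies how much
group-specific information lives on each side. Two failure modes of PCA are
made measurable and reproducible:

* **sample-size failure** — a biologically distinct minority group (e.g.
  liver at ~4% of samples) only earns a leading component when enough of its
  samples are present; below a threshold fraction its direction vanishes
  from the top PCs entirely;
* **effect-size failure** — a contrast with huge per-gene effects on a
  handful of genes but a small overall effect (e.g. sex: XIST and
  Y-chromosomal genes) never reaches the leading components, yet is easy to
  find with a kurtosis-based bimodality screen.

## The decomposition and the information ratio

For a genes × samples matrix **X**, gene-centered to **X**<sub>c</sub>, with
orthonormal loadings **L**<sub>k</sub> of the first *k* PCs (samples as
observations, no variance scaling):

    P = L_k L_k^T X_c        (projected matrix: rank-k reconstruction)
    R = X_c − P              (residual matrix: components k+1, k+2, …)

Both have the full size of **X**, so any per-gene statistic can be computed
in either subspace. For a two-group contrast, per-gene Welch t-test p-values
are computed on **P** and **R**, summed as S<sub>•</sub> = Σ<sub>genes</sub>
(−log₁₀ p<sub>•</sub>), and combined into the **information ratio**

    IR = S_R / (S_P + S_R)   ∈ [0, 1]

low IR: the leading components carry the contrast; high IR: the information
survives in the residual. Scanning IR over *k* localises the components that
carry a signal.

Around this core the package provides group-signature correlation analysis,
residual-subset PCA with cross-dataset validation (project an independent
cohort onto residual-subset components via scalar products), proportion-
matched downsampling, sample-size perturbation scans, a kurtosis screen
(moment-ratio kurtosis m₄/m₂², minimised at 1 by two-point distributions),
simplified linear projection onto predefined biological direction sets, and
a fully ground-truthed synthetic-data generator emulating the statistical
structure of real compendia (large-scale groups, nested subtypes, minority
groups, few-gene genetic signals, study batches, noise).

## Worked example

```python
import numpy as np
import residualscope as rs

x, truth = rs.generate(rs.preset("compendium"))   # 2000 genes x 600 samples
model = rs.fit_pca(x, 3)
print("explained fractions:", np.round(model.explained_fraction, 3))

res = rs.ir_for_groups(x, model, 3, truth.annotation,
                       "cerebellum", "frontal_cortex")
print(f"IR(cerebellum vs frontal_cortex, k=3) = {res.ir:.3f}")
res2 = rs.ir_for_groups(x, model, 3, truth.annotation, "cerebellum", "t_cell")
print(f"IR(cerebellum vs t_cell, k=3) = {res2.ir:.3f}")

report = rs.rank_bimodal(x, top_n=5)
print(report.top.round(3))
```

prints

```
explained fractions: [0.248 0.132 0.067]
IR(cerebellum vs frontal_cortex, k=3) = 0.477
IR(cerebellum vs t_cell, k=3) = 0.069
         kurtosis  rank
gene_id
G00056      1.055     1
G00375      1.064     2
G00152      1.078     3
G00464      1.079     4
G00473      1.779     5
```

The three leading components explain ~45% of the variance (they capture the
three large-scale group directions). A contrast **between** large-scale
groups (cerebellum vs t_cell) lives almost entirely in the projected space
(IR = 0.07), while a contrast between two brain regions — subtypes sharing
the same large-scale signature — keeps about half of its evidence beyond the
top three components (IR = 0.48). The five lowest-kurtosis genes are exactly
the five genes carrying the planted genetic (sex-analogue) signal, which no
leading PC separates.

The same analyses are available from the shell:

```bash
residualscope simulate --preset compendium --out-prefix sim
residualscope ir --expression sim.expression.tsv --annotation sim.annotation.tsv \
    --k 3 --group-a cerebellum --group-b t_cell --out-prefix ir_run
residualscope recipe liver_scan --out scan_out --seed 1
```

## Data conventions

Expression matrices are tab-separated, genes as rows, samples as columns,
log2 scale (RMA-style output), no missing values. Annotations are TSV with
`sample_id`, `group`, `large_scale_group` and optional `sex`, `study_id`
columns; probe-to-gene maps are TSV with `source_id`, `target_id`. See
`docs/methods.md` for the model details, parameter choices, and limitations.
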