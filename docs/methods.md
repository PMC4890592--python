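# Methods

This note documents the statistical model behind `residualscope`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions used throughout.

## PCA convention

Samples are observations and genes are variables: each gene is centered by
its mean across samples; no unit-variance scaling is applied (log2/RMA
intensities already share a common scale, and scaling would inflate
low-variance genes). The fit is computed by singular value decomposition of
the centered genes × samples matrix, which is stable in the usual regime of
many more genes than samples. Eigenvalues are singular values squared over
(n − 1); `explained_fraction` divides by the total centered variance, so the
fractions of a k-component model deliberately do not sum to one.

PC signs are mathematically arbitrary. Each loading column is flipped so its
largest-magnitude entry is positive (ties broken by the first index), making
every downstream artifact byte-reproducible.

Reconstruction identities (projected + residual = centered data, trace
orthogonality of the two parts, agreement with a brute-force covariance
eigendecomposition) are maintained to 1e-8 relative to the Frobenius norm of
the centered matrix.

## Projected and residual matrices

`decompose(x, model, k)` returns `P = L_k L_k^T X_c` and `R = X_c − P`, both
full-sized. `k = 0` is legal (empty projected space). Cross-dataset
projection (`project_external`, `validate_on_external`) centers the new
cohort by its **own** per-gene means before taking scalar products with the
foreign loadings — the foreign model's center never transfers across
platforms. For residual-subset PCA the residual submatrix is re-centered
within the subset: the residual has zero overall mean but not zero subset
mean. On the full sample set this construction provably reproduces the
parent components k+1, k+2, … (orthogonal-complement identity, tested); on a
proper subset it can surface directions the full-dataset PCA ranks below its
leading components.

## The information ratio

Per-gene two-group p-values are computed with Welch's unequal-variance
t-test (vectorised; a pooled-variance option exists). Welch is the safer
default for heterogeneous compendia where group variances differ
substantially. Conventions for degenerate cases:

* p-values are floored at 1e-300 before any log transform;
* a gene constant in both groups carries no information: p = 1;
* a standard error at double-precision dust level (se² ≤ 1e-24, as in the
  residual matrix at full rank) is treated as an exact zero.

The scalar summary is IR = S_R / (S_P + S_R) with S = Σ(−log₁₀ p), defined
as 0.5 when both sums vanish. The construction guarantees the documented
range and directionality (0 = all information in the projected space, 1 =
all in the residual). Two intrinsic behaviours are worth knowing:

* with G genes and no signal anywhere, both sums sit near 0.434·G, so the
  no-signal regime hovers around 0.5 rather than collapsing to 0;
* at very small k the projected matrix is nearly rank-1 per gene, which
  slightly overstates per-gene evidence in the projected space; IR-vs-k
  scans therefore show a small dip at k = 1–2 before stabilising. Neither
  affects the scan's ability to localise signal-bearing components.

No multiple-testing correction is applied: the IR consumes raw p-values and
makes no per-gene significance claims.

## Signatures and correlation analyses

A group signature is the vector from the overall dataset mean to the group
mean; on the residual matrix the overall mean is ~0 and the signature is the
residual group mean. Signature heatmaps are ordered by complete-linkage
hierarchical clustering under euclidean distance (SciPy's tie-breaking by
original index makes the leaf order deterministic). Within-group correlation
is the mean Pearson correlation over all unordered sample pairs; in the
original space samples are first referenced to the overall per-gene mean so
that the statistic is comparable with its residual-space counterpart (which
is used as-is). The default group-size filter is 10 samples.

## Bimodality screen

Moment-ratio kurtosis m₄/m₂² with biased central sample moments, no excess
subtraction: the variant choice shifts absolute values but not the ranking,
which is the quantity of interest (low kurtosis = bimodal; the balanced
two-point distribution attains the minimum of 1, a normal gives 3, and a
balanced normal mixture with half-separation d and component sd σ gives
(d⁴ + 6d²σ² + 3σ⁴)/(d² + σ²)², used as a closed-form test oracle). Constant
genes are excluded from the ranking rather than failing the screen; ties
break lexicographically by gene id. The per-gene split is 1-D 2-means with
deterministic extreme-value initialisation (no seed dependence), the
smaller-mean cluster labelled 0.

## Direction projection

Predefined direction sets (e.g. tissue-specific expression patterns) are
unit-normalised per column over the gene set common to data and directions;
sample deviations from the overall dataset mean are scored by scalar
products. This is a deliberately simple linear variant of direction-space
scoring — rank-based variants exist and are out of scope. Mislabel flagging
uses robust z-scores (median / 1.4826·MAD) of same-label scores; samples
more than `z_threshold` robust units *below* the label median are flagged.
The quantitative rule is this package's own addition to what is usually an
eyeballing step.

## Synthetic-data generator

The generator produces log2-scale matrices

    x[g,s] = mu[g] + delta_L u_L[g] + delta_c u_c[g] + delta_m w[g]·1[s∈minority]
             + d·1[g∈genetic set]·1[s carrier] + beta[study(s),g] + eps[g,s]

with baselines mu ~ N(7, 1.5²) (typical RMA intensity scale), unit-norm
sparse direction vectors u, w (default sparsity 0.1, so an energy of 15
means ~1 log2 unit on each of 200 carried genes), per-study batch offsets
beta ~ N(0, σ_b²), and i.i.d. noise eps ~ N(0, σ²). With `effect_continuum`
(default) per-gene magnitudes on a direction's support are exponential —
the continuum of differential expression characteristic of non-genetic
contrasts — rather than equal.

Two structural choices matter and were derived, not tuned:

* **Hierarchical centering.** Subtype effect vectors are deviations from
  their large-scale group's size-weighted centroid (renormalised to the
  configured energy). Without this, the mean of a group's subtype directions
  leaks into the large-scale centroid direction; the leading PCs then
  capture that mixture and projecting them out strips a third of the subtype
  amplitude from its own samples. With centering, "subtype structure is
  orthogonal to the leading components" holds by construction, sibling
  subtype deviations are mildly anti-correlated (≈ −1/2 for three balanced
  siblings), and within-subtype residual coherence is governed only by
  δ²/(δ² + Gσ²).
* **Carrier stratification.** Genetic carrier status (the sex analogue) is
  apportioned within studies by largest-remainder rounding to the exact
  total. Unstratified assignment lets chance sex-by-study imbalance place
  sex information into batch components, confounding the two failure modes.

`generate(config, cohort_seed=...)` redraws the sampling layer (study
assignment, carriers, batches, noise) while keeping the structural layer
(baselines, directions, genetic gene set) fixed — an independent cohort
measuring the same biology, used for cross-cohort validation.

### Preset calibration

Preset effect energies were placed with spiked-covariance arithmetic rather
than trial and error. For a group holding fraction π of n samples with
effect energy δ, the between-group covariance carries a spike of size
β ≈ π(1−π)δ² along its direction; sample-covariance noise occupies a
Marchenko–Pastur bulk with edge σ²(1+√γ)², γ = G/n, and a spike is
detectable/aligned according to x = β/σ² relative to √γ (the
Baik–Ben Arous–Péché transition), with population alignment
cos² = (1 − γ/x²)/(1 + γ/x).

* `compendium` (2000 genes × 600 samples, σ = 0.25, 10 studies, σ_b = 0.05):
  three large-scale groups with staggered energies (34, 27, 21) over a large
  unstructured background so the three directions stay individually
  identifiable in the top-3 loadings (the global-centering term −aa^T with
  a_c = π_cδ_c mixes eigenvectors; small fractions and staggered energies
  keep the mixing below ~0.2 rad); nine subtypes at energy 15 (spikes ≈ 7–10,
  far above the bulk edge 0.72, far below the weakest large-scale spike 33);
  a 23-sample liver minority (3.8%); a 5-gene genetic signal of 4 log2 units.
* `liver_scan` (σ = 0.2): the liver minority (23 samples, energy 7) competes
  with a muscle-analogue group for the fourth component. The muscle spike is
  placed between the liver spike at 60% and at 100% of its reference count,
  so the liver direction enters the top 4 only above ~70–80%. The competitor
  uses 12 samples at energy 8.7 rather than more samples at lower energy:
  the centering cross-term couples two directions in proportion to the
  product of their π·δ values, and the small-fraction form suppresses that
  deterministic eigenvector mixing, leaving only O(n^−1/2) stochastic
  mixing (cosine leakage ≤ ~0.2 at 60%, alignment ≈ 0.9 at 100%).
* `sex_lymphoma` (208 samples, 90/118 non-carrier/carrier, 8 studies,
  σ_b = 0.5): eight genetic genes shifted by 4 log2 units give a spike ≈ 31,
  above the noise bulk (edge ≈ 1.5) but below the ~55-strong study-batch
  spikes, so the sex direction sits around component 8 — invisible to the
  top 4, localised by the IR scan, and trivially found by the kurtosis
  screen (planted kurtosis ≈ 1.3 vs ≥ 1.9 for any batch-realised null
  configuration).

### What the generator does not emulate

Gene–gene regulatory correlation (beyond what planted directions induce),
probe-level artifacts, GC or intensity-dependent biases, heavy-tailed noise,
platform differences, or annotation errors. Passing tests on this generator
demonstrate that the analysis chain measures what it claims under the
documented covariance structure — not that real compendia have exactly this
structure. Desk-scale sizes (2000 genes, ≤ 600 samples) keep every analysis
in seconds; the mechanisms scale with the dimensionless quantities (π, δ²/σ²,
G/n), not with absolute size.

## Other conventions and degenerate inputs

* Downsampling sorts candidate ids before seeded draws, so results depend
  only on the seed and the requested counts, never on file order.
* The sample-size scan defines alignment as the maximum |point-biserial
  correlation| between a leading score vector and the target indicator; a
  constant indicator (target = everything) yields 0 by convention. When a
  ground-truth direction is supplied, the maximum |cosine| against the
  leading loadings is reported alongside.
* Probe translation averages multi-mapped sources per target (a documented
  choice; `ambiguous="drop"` is available); sources feeding several targets
  contribute to each; identifiers are case-sensitive.
* Missing values are rejected, never imputed: silent imputation would break
  the exact decomposition identities.
* `loading_r2` is ordinary least squares with intercept, clamped to [0, 1]
  against floating-point excursions; a constant target is an error.

## Known limitations

The IR formula is one concrete realisation of the 0-to-1
projected-vs-residual summary; published figures computed with other
aggregation variants are comparable in direction but not digit-for-digit.
The Welch test assumes per-gene normality; for strongly non-normal data the
per-gene p-values (and hence IR magnitudes, not usually its ordering) shift.
The bimodality screen targets two-mode distributions; multi-modal or skewed
unimodal expression needs mixture- or dip-style statistics, deliberately out
of scope. Real-data headline figures that require the original multi-
thousand-sample compendia (e.g. the ~36% variance of their first three PCs)
can be recomputed with `read_expression` + `fit_pca` when those matrices are
locally available, but are not part of the default test run.
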