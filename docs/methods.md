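# Methods

`scref` implements a complete scheme for estimating cell-type fractions in
bulk tumor expression data from single-cell-derived reference profiles:
per-cell signature scoring, staged cell-type identification, marker
selection, reference construction, ν-SVR deconvolution, and an in-silico
benchmark with known ground truth. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## The deconvolution model

A bulk expression profile is modeled as a linear mixture

    m = f × B

where `m` is the mixture over a panel of genes, `B` is the reference GEP
matrix (panel genes × cell types, each column the mean expression of one
cell type), and `f` is the vector of cell-type fractions. The model is only
exact in **linear** expression units: single-cell values stored as
`y = log2(TPM + 1)` are un-logged to `x = 2^y − 1` before any averaging or
mixing arithmetic (pseudo-bulk pooling, GEP construction). Every matrix
carries an explicit scale flag and consumers dispatch on it.

`f` is estimated by ν-support-vector regression with a linear kernel, the
algorithm popularized by CIBERSORT: the reference matrix is z-scored by its
global (scalar) mean and standard deviation, the mixture by its own, a
ν-SVR is fitted for each ν in {0.25, 0.5, 0.75} with C = 1, negative
coefficients are clipped to zero, the vector is renormalized to sum one,
and the ν whose reconstruction `X·f̂` has the smallest RMSE against the
standardized mixture is kept. Standardizing the mixture by its own
statistics makes `f̂` exactly invariant to rescaling `m → c·m` (`c > 0`),
which is the natural contract for TPM-like units; we verify it numerically
to 1e-6. We deliberately do **not** z-score each gene by its across-type
statistics: per-gene standardization destroys the non-negative mixture
geometry and, in our experiments on exact mixtures, inflates the maximum
per-type error from ~1e-4 to ~0.3.

Two degenerate regimes are handled explicitly: a constant mixture (or
reference) and an all-non-positive coefficient vector both return uniform
fractions with a warning rather than failing. Note that a reference whose
rows sum to a constant (e.g. a 2×2 identity) is structurally
non-identifiable for any regression with an intercept — the intercept is
collinear with the column sum — so tiny orthonormal toys are recovered only
up to coefficient differences; identifiability requires heterogeneous gene
magnitudes, which real references always have.

Reported fractions are relative abundances summing to one. No cell-size /
RNA-yield correction is applied, so they approximate cell-count proportions
only to the extent that per-cell RNA content is comparable across types.

## ssGSEA scoring

Per sample, genes are ranked by expression (descending; ties broken by gene
symbol so scores are invariant to input row order; rank weights use average
ranks). Walking the ranked list, the enrichment score is the summed
difference between the weighted in-set cumulative distribution
(`P_in(i) = Σ_{g∈G, rank≤i} r_g^α / Σ_{g∈G} r_g^α`, with `r_g` the
bottom-up average rank and α = 0.25) and the uniform out-of-set
distribution (`P_out(i) = #{g∉G, rank≤i}/(N−|G|)`). This is the
total-running-sum ("Barbie-style") ssGSEA statistic; no across-sample
normalization is applied, and all-zero genes participate with the lowest
ranks so per-cell scores remain comparable. Scores are rank-based, hence
invariant under any strictly monotone per-sample transform.

## Moderated differential expression

Two-group comparisons use an empirical-Bayes moderated t. Per-gene pooled
variances `s²_g` (df `d = nA + nB − 2`) are shrunk toward a prior fitted to
the whole variance distribution: matching the mean and variance of
`log s²` to the moments implied by a scaled-F model (digamma/trigamma
moment equations, trigamma inverted by Newton iteration) yields the prior
df `d0` and prior variance `s0²`; then `s̃²_g = (d0·s0² + d·s²_g)/(d0 + d)`
and `t = Δmean / (s̃_g √(1/nA + 1/nB))` with `d0 + d` degrees of freedom.
`d0 = 0` recovers the ordinary pooled t exactly (tested to 1e-9); an
infinite `d0` is capped at 1e6. Benjamini–Hochberg step-up correction is
applied across genes (delegated to statsmodels; tested against the
definitional O(n²) step-up oracle). Significance filters use strict
inequalities: |log2FC| > 1 and adjusted p < 0.05 for subtype contrasts,
log2FC > 3 (up-regulated only) for marker selection.

## Staged cell-type identification

Identification proceeds in three stages, easiest split first:

1. **Malignant vs non-malignant.** All cells are reduced to 50 principal
   components, embedded in 2-D by t-SNE (perplexity 50, seeded), and
   clustered by DBSCAN (eps 5, minPts 5). A cluster is malignant iff the
   tumor signature is the argmax of its mean ssGSEA score over all
   candidate signatures. Diagnostics report each cluster's
   majority-patient share: malignant clusters are expected to be
   patient-dominated while immune clusters mix patients.
2. **Major types.** Non-malignant cells are re-embedded (perplexity 30,
   eps 6, minPts 15) and each cluster labeled by the argmax over the seven
   major-type signatures (fibroblast, B cell, macrophage, endothelial,
   dendritic, mast, and a lumped T-cell signature formed as the union of
   the four T-subtype signatures). DBSCAN noise cells stay `unassigned`
   and are excluded from reference construction.
3. **T subtypes.** The lumped T cells are consensus-clustered SC3-style:
   Euclidean, Pearson (1−r) and Spearman distance matrices are each
   projected on their leading principal components for dimensions spanning
   4–7% of the cell count (at most four values for runtime), k-means
   (k = 4, seeded) runs on every projection, and the co-clustering
   frequency matrix is cut at k = 4 by average-linkage hierarchical
   clustering. Clusters are split into a CD4 and a CD8 side by pooled-
   signature argmax; within each side a moderated-t contrast orients the
   pair — the cluster whose exhaustion program (default PDCD1, TIGIT,
   CTLA4, HAVCR2; user-overridable via GMT) is predominantly up-regulated
   is exhausted CD8, and the cluster up-regulating the Treg program
   (default FOXP3, TIGIT, CTLA4) is Treg. If the side split is not 2-vs-2
   the code falls back to per-cluster argmax over the four subtype
   signatures with a warning. The two DE tables are returned (the
   T-subtype marker panel).

t-SNE embeddings vary between runs by construction; every embedding is
seeded and tests pin seeds. The eps/minPts values are tied to the
coordinate scale t-SNE produces for cohorts of a few thousand cells; small
inputs (hundreds of cells, or data with many duplicated cells) spread over
much wider coordinates and need a proportionally larger eps.

## Marker selection and reference construction

Marker genes per type come from all pairwise moderated-t comparisons among
the annotated types: a gene is a marker of type k when it is up-regulated
(log2FC > 3, BH p < 0.05, strict) against at least 5 other types. A gene
qualifying for several types is assigned to the type with the most
qualifying comparisons, ties broken by the larger median log2FC over its
qualifying comparisons — the resolution rule is this package's choice, as
the criterion itself admits multi-type qualification. Tumor-vs-non-tumor
markers reuse the same machinery with two groups and a single required
comparison. Panels (curated signatures, leukocyte panels, derived markers)
are merged by set union with per-gene provenance tags and intersected with
the expression matrix; the reference GEP is the per-type mean of linearized
expression over the merged panel. Gene identity is by symbol,
case-sensitive, with no alias resolution; duplicate gene rows in input
files collapse by per-entry maximum.

## The synthetic cohort generator

The generator emulates the statistical structure of a Smart-seq2-style
single-cell tumor cohort — the structure every pipeline stage relies on —
with known ground truth. Defaults (all log2(TPM+1) units):

| parameter | default | meaning |
|---|---|---|
| n_patients | 16 | patients (one pseudo-bulk each) |
| cells_per_patient | 300 | cells per patient |
| n_genes | 1200 | genes |
| cell_types | 11 types | malignant + 6 major + 4 T subtypes |
| n_markers_per_type | 20 | disjoint planted markers per type |
| marker_log2fc | 4.0 | marker elevation over baseline |
| patient_shift_sd | 1.0 | per-patient offset, malignant cells only |
| noise_sd | 1.0 | per-cell per-gene Gaussian noise |
| dropout_rate | 0.1 | probability any entry is zeroed |
| malignant_fraction_range | [0, 1] | tumor purity range across patients |

Per-cell profiles are `baseline + marker boost + patient shift (malignant
only) + noise`, zeroed with probability `dropout_rate` and clipped at 0.
The shared per-gene baseline is N(1.5, 1) clipped at zero on the log2
scale (heavy-tailed in linear units). Malignant fractions are drawn one
per equal-width stratum of the configured range and shuffled across
patients, so the empirical purities cover the range with maximal gap below
2/n_patients; the remaining mass is split over the ten non-malignant types
by a flat Dirichlet. Integer per-type cell counts come from
largest-remainder rounding, and the recorded true fractions are exactly
the cell-count proportions.

Parameter choices that were open: `patient_shift_sd = 1.0` makes a
patient's malignant profile deviate ~2-fold per gene from the cohort mean —
enough that malignant cells cluster by patient while immune cells cluster
by type (the shift adds purely between-patient variance), yet small enough
that a cohort-mean malignant reference remains representative. Much larger
shifts (e.g. sd 2, ~4-fold) make pseudo-bulk deconvolution infeasible for
*any* method — the non-negative least-squares oracle itself degrades — and
therefore do not emulate data on which reference-based deconvolution is
known to work. `dropout_rate = 0.1` under the uniform-zeroing dropout
model keeps the observed marker contrast near `(1−p)·4 ≈ 3.6`, preserving
the intended ≥3 log2 separation; the uniform model is a simplification —
real dropout is expression-dependent, which would attenuate high markers
even less.

What the generator does **not** emulate: UMI counting noise, library-size
variation, doublets, batch/enzyme effects, expression-dependent dropout,
correlated gene programs within a type, or a continuum of cell states.
Passing tests therefore demonstrate the pipeline's correctness and its
behavior under the modeled noise sources, not performance on real tumors.

## Benchmark and evaluation

Pseudo-bulks are per-patient gene-wise means of linearized single-cell
expression, so the mixing identity `bulk = Σ_k f_k · (mean linear profile
of type k)` holds to machine precision by construction. Accuracy is the
Pearson correlation between true and estimated fractions, reported per
cell type (across samples), pooled over all (sample, type) pairs, and for
the aggregate T-cell fraction (sum of the four subtypes). Correlations
need at least 3 samples and non-constant inputs; degenerate cases are NA.
The benchmark can score either the generator's truth labels or the
pipeline's own annotation, isolating annotation error from deconvolution
error. A leave-one-out harness drops one reference column at a time,
re-deconvolves, and reports each remaining type's correlation and its
change versus the full reference.

Problem sizes used throughout the tests and the acceptance script — 16
patients × 300 cells, 1,200 genes, and sub-sampled cohorts for unit tests —
are the package's default study conditions; they keep every stage's
behavior measurable while each run stays in the minutes range on one CPU.

## Known limitations

- Relative, not absolute, abundances (no cell-size factor).
- eps/perplexity are fixed constants, not auto-tuned; they suit cohorts of
  a few thousand cells.
- The SC3 reduction uses three distances and PCA transforms only (no
  Laplacian variant, no gene filtering).
- Marker selection assumes a single label per cell and hard cluster
  boundaries.
- The moderated t omits limma's trend and robust variants.
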