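# Methods

## Model

`voxmap` aligns a non-negative cells × genes matrix *S* (sc/snRNA-seq) with a
non-negative voxels × genes matrix *G* (spatial) over their shared gene
panel.  A "voxel" is one spatial measurement unit — a segmented cell for
targeted in situ data, a multi-cell spot for array-based data.  The learned
object is a row-stochastic mapping *M* (cells × voxels): M_ij is the
probability that cell *i*'s profile explains voxel *j*.  Row-stochasticity is
enforced structurally by parametrizing M = softmax(M̃) along the voxel axis
(max-subtraction stabilized), never by projection.

The plain objective combines three terms:

- **density**: KL(m ‖ d), m_j = Σ_i M_ij / n_cells, against a prior d on the
  probability simplex.  d is uniform for single-cell-resolution data and
  proportional to segmented-cell counts for spots.
- **gene-axis expression**: Σ_k cos_sim((MᵀS)_{*,k}, G_{*,k}) — each gene's
  predicted spatial pattern should be proportional to its measured pattern.
- **voxel-axis expression**: Σ_j cos_sim((MᵀS)_{j,*}, G_{j,*}) — each
  voxel's predicted profile should be proportional to its measured profile.

Cosine similarity is scale-invariant, so *S* and *G* may use different units
(counts vs normalized intensities); the package verifies this invariance as
a property test.  Expression terms enter the loss negatively (similarity is
rewarded); the density term positively.

When profiles outnumber spatial cells, a per-cell filter f = σ(f̃) selects
the mapped subset.  The filtered objective replaces S with diag(f)·S and the
density with m^f_j = Σ_i f_i M_ij / Σ_i f_i, and adds

- a **count term** |Σ_i f_i − n_target_cells| softly fixing how many cells
  survive,
- a **filter regularizer** Σ_i (f_i − f_i²), minimized exactly at Boolean
  filter values,
- optionally λ · Σ_ij (−M_ij log M_ij), a row-entropy regularizer that
  sharpens each cell's spatial distribution (default λ = 0; maps peak on
  their own in all regimes we exercise).

### Use-case presets

- *targeted* (single-cell-resolution data): uniform d; filtered mode with
  n_target_cells = n_voxels when cells outnumber voxels, else plain mode.
- *spots* (probabilistic spot mapping): plain mode, segmentation-derived d.
- *deconvolution*: filtered mode, segmentation-derived d, n_target_cells =
  total segmented cells; after training, cells with f > 0.5 are placed in
  their argmax voxel and matched uniformly at random (seeded) to that
  voxel's segmented cells.

## Optimization

Full-batch Adam (β₁ = 0.9, β₂ = 0.999) on analytically derived gradients,
chained through the softmax rows and sigmoid.  The count term uses the
subgradient sign(Σf − n_target).  Gradient code is validated against central
finite differences to 1e-4 relative error (in practice ~1e-9) as part of the
test suite.  Everything is double precision and driven by a single seeded
`numpy` generator, so a fit is bit-reproducible from its configuration
snapshot; the deconvolution assignment uses a separate named stream so
mapping and placement seeds are independent.

Defaults: learning rate 0.1; epochs by preset — 1,200 targeted, 300 spot
mapping, 6,000 deconvolution, 150 atlas-style — all overridable.  No early
stopping; convergence is reported (loss trace per epoch plus a sharpness
statistic: the fraction of retained cells with max_j M_ij > 0.5), not
enforced.  ε = 1e-8 clamps every log argument and cosine denominator; a
cosine involving an all-zero vector is defined as 0 with zero gradient
(holdout predictions of unexpressed genes would otherwise be undefined).

The objective is nonconvex.  On self-mapping fixtures up to 8×8 the fitted
assignment matches the optimum found by exhaustive enumeration of all hard
assignments; in filtered mode the Boolean-promoting regularizer can entrench
an early wrong selection on adversarially sparse fixtures, so the acceptance
script reports subset-recovery as a rate over seeded instances rather than a
single run.  Multi-start selection is deliberately out of scope.

## Preprocessing and panel selection

Library-size normalization rescales each profile to a common total (default
1e4 — a convention; only "correct for library size" is required), followed
by log1p where used.  Marker ranking standardizes each gene (z-score),
applies a Welch unequal-variance t-test of each type against all other
cells, and ranks by the signed statistic (upregulated markers first), ties
broken lexicographically for reproducibility.  The training panel is the
union of each type's top-k markers (k = 100 by convention; the synthetic
suite uses k = 10 to match its 20-marker blocks) intersected with the
spatial panel, in first-appearance order.  Gene matching is exact,
case-sensitive string equality.  Whether cosine terms see raw, normalized,
or log counts is a config choice; defaults use the matrices as provided,
since cosine removes per-row scale anyway.

## Validation design

**Scoring.**  A held-out gene's predicted per-voxel pattern (column of MᵀS)
is compared with its measurement by Pearson correlation across voxels
("spatial correlation"; Spearman behind a flag).  Zero-variance vectors are
flagged undefined, not scored 0.  Gene sparsity is the fraction of voxels
where the gene is exactly 0, computed on the matrix as given; summaries
stratify genes at sparsity 0.5 and report quantiles with linear
interpolation.  Leave-one-out refits once per panel gene from the same init
seed; the training-fraction sweep subsamples the panel per seeded fraction
but holds the test set fixed (the shared complement of the *full* panel) so
that score changes reflect training-set size, not the drift of easy marker
genes into the test set.

**Synthetic suite.**  The generator builds what the method assumes: a few
cell types with distinct signatures (disjoint marker blocks elevated
`effect`-fold over a shared baseline), a tissue of contiguous voxel bands
each dominated by one type (occupancy `purity` for the dominant type,
remainder spread evenly), cells placed per voxel (1 + Poisson draws), an
sc measurement as Poisson counts at depth `sc_depth`, and a spatial
measurement as either one voxel per placed cell (targeted-style) or per-spot
sums of resident cells' signatures (array-style), degraded by Poisson noise
at a depth multiplier, i.i.d. Bernoulli dropout, and an arbitrary unit scale.
The standard suite is 5 types × 200 genes (20 markers/type, effect 8), 100
layered voxels (purity 0.8), ~300 cells, sc depth 10, seed 0 — chosen once
as a realistic desk-scale regime and kept fixed.  Regeneration from its
parameter record is bit-identical.

Cell-type recovery is scored on the single-cell-resolution rendering, where
the deterministic per-voxel call is defined; on multi-cell spots the
per-voxel argmax legitimately reports minority-type residents of mixed
voxels, so spot-level structure is validated through imputation and
deconvolution statistics instead.

**What passing does not show.**  The generator has no batch effects, no
ambient RNA or doublets, no negative-binomial overdispersion (Poisson plus
dropout only; NB is a config extension point), no continuous cell states,
and spatial structure limited to banding.  Synthetic recovery therefore
validates the optimization and the transfer algebra — that the machinery
finds plantable structure — not performance on real tissue, where marker
quality and segmentation accuracy dominate.

## Degenerate inputs and numerical conventions

All-zero rows are rejected at normalization (named in the error); all-zero
gene columns survive and are flagged at scoring.  Disjoint gene panels and
empty matrices are hard validation errors.  Deterministic calls break ties
to the lowest cell index; a voxel whose every candidate cell is filtered out
is flagged `<unassigned>`.  In deconvolution, surplus mapped cells in a
voxel (more than its segmented count) are dropped in order of decreasing
probability and reported, never silently lost; surplus segmented cells stay
unassigned.  MTX files are 1-based on disk per the format standard, 0-based
in memory; integer matrices round-trip bit-exactly through MTX/CSV/TSV.

## Problem sizes used in the checked results

Brute-force cross-checks enumerate all n! hard assignments up to n = 8
(40,320 configurations) and all C(6,3) × 3! filtered configurations on the
planted-subset fixture.  Suite-level statistics use the standard suite
(~300 cells, 100 voxels, 50-gene panel); leave-one-out summaries use a
seeded 24-gene subsample of the panel (one refit per gene), with the full
panel available through the same API.  These sizes are the package's
standard desk-scale fixtures; every number the README or acceptance script
cites is recomputed at run time at these sizes.
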