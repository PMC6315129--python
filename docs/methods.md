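# Methods

## Overview and coordinate conventions

`faceasym` quantifies bilateral facial asymmetry as deviation from a
population model, not from perfect symmetry: some asymmetry (lip corners,
eye region) is normal, and its expected amount varies across the face. The
pipeline is: rigid landmark alignment → dense correspondence → cohort
average mesh → mirror comparison → local feature maps → normal model →
spatiogram score.

All geometry is in millimetres. The aligned frame puts the midsagittal
plane at `x = 0` with `+x` the subject's anatomical left, `+y` superior,
`+z` anterior. The reference landmark configuration (by default the
synthetic template's) fixes this frame; mirroring is reflection about
`x = 0`, and any residual midline offset after alignment is absorbed by the
correspondence step rather than by estimating a symmetry plane.

## Alignment and correspondence

Alignment is least-squares **rigid** Procrustes (rotation + translation,
no scaling) on the 18 named landmarks. Scaling is deliberately excluded:
deformation magnitudes are physical millimetres and a similarity fit would
shrink exactly the large-asymmetry faces the score must flag.

Dense correspondence from a base mesh to a subject is a thin-plate-spline
warp of the base vertices driven by the landmark pairs (3D kernel
`U(r) = r`, exact interpolation; regularization `lam` exposed for noisy
landmarks, default 0), followed by exact closest-point projection onto the
subject's triangle set. Projection prunes candidates with a KD-tree over
triangle centroids and falls back to a radius search whenever the pruning
bound cannot certify the winner, so the result equals an all-triangle scan
(tested against one). The cohort average mesh is the vertex-wise mean of
corresponding positions; one re-mapping iteration from the current average
is the default (`average_iterations=1`). An optional smoothing+reprojection
refinement pass exists but is off by default for determinism.

Features are evaluated at average-mesh points by sampling each subject's
original and mirrored surfaces through the two dense correspondences.
Normals at correspondence targets are barycentric-interpolated vertex
normals, renormalized — interpolation avoids the quantization noise of
flat per-facet normals. Where the flow vector is shorter than `1e-6` mm the
deformation angle is defined as 0: a symmetric point contributes "no
asymmetry", not a missing value.

## Normal model and score

The model stores the per-point sample mean and SD (`ddof=1`) of each
feature over the cohort, with the SD floored at `1e-6` so standardized
errors stay finite where the cohort is perfectly concordant. Histogram
ranges are fixed per feature — `[0°, 180°]` for the two angles, `[0, cohort
max]` for the magnitude — in `B = 25` equal-width bins, so histograms are
comparable across subjects; an out-of-range value is an error, not a clip.
Bins are half-open `[e_k, e_{k+1})` with the last bin closed.

The spatiogram distance follows the region-based formulation: per bin, the
coherent regions are connected components (size ≥ τ) of the bin's points on
the mesh vertex-adjacency graph; Ψ_b is the region-size-weighted mean of
the per-region average standardized error |A−A′|/σ; incoherent points count
toward bin frequencies but are excluded from Ψ. The per-bin weight on Ψ_b
is the Bhattacharyya dissimilarity `1 − sqrt(p_b p'_b)` of the *normalized*
frequencies (a literal product of raw counts would be negative for any
occupied bin and dimensionally inconsistent); a `1 − min/max` variant is
selectable via `variant="minmax"` for sensitivity analyses. Directed
distances use the first argument's regions; the score is the symmetrized
mean of both directions, which makes ρ(h,h′) = ρ(h′,h) exact by
construction.

**Coherence threshold.** A component is coherent iff its size is ≥ τ
(inclusive reading), with τ = 20 the canonical default — about 0.1% of a
~20,000-point facial scan. τ is a *fraction of the image* in disguise: at
desk-scale resolutions the pipeline (`score_cohort`) therefore defaults to
`τ = max(2, 0.001 · N_scored)` rather than the absolute 20, which at
~2,000 scored points would be ~1% of the image and make the score
discontinuous (regions near the threshold flicker between coherent and
incoherent). Passing `tau` explicitly overrides this.

All histogramming and scoring is restricted to the below-eyes crop
(vertices with `y ≤` the mean endocanthion height; faces straddling the cut
are dropped, since sub-facet clipping cannot change per-vertex features).
On real scans the crop avoids eyelash/eyebrow/hairline noise; the synthetic
generator produces clean meshes but the crop is applied regardless so the
scored region matches the method.

## Baselines

- `mean_magnitude`: arithmetic mean of the deformation magnitude over the
  scored region (mm).
- `landmark_procrustes`: the 12 bilaterally paired landmarks are reflected
  and relabelled left↔right, rigidly re-aligned to the original
  configuration by least squares (no scaling; a scaling toggle is not
  provided because the step-by-step procedure is defined rigidly), and the
  mean residual paired distance is the score. Reflection about any plane
  differs from reflection about `x = 0` by a rigid motion, so the score is
  frame-invariant.

## Association stage

A from-scratch linear-model scan, not a wrapper around an external GWAS
tool. SNPs whose minor allele is carried by fewer than 5 subjects are
removed (carrier count — the literal "present in fewer than N subjects";
an allele-count mode is available). Ancestry is adjusted with the first 4
principal components of the mean-imputed, column-standardized genotype
matrix; PC signs are fixed by forcing the largest-magnitude loading
positive, making the decomposition deterministic. Each SNP is tested by OLS
of the score on `[1, g, age, sex, PC1..PC4]` with a two-sided t-test on the
genotype coefficient; subjects with a missing genotype are dropped per SNP
(complete cases), and mean imputation is used only inside the PCA. The scan
is vectorized by Frisch–Waugh–Lovell residualization, which reproduces the
full-design OLS estimate, SE and t exactly (verified against per-SNP OLS
and statsmodels). Benjamini–Hochberg step-up adjustment is applied to the
p-values pooled across all phenotype scores — one global family. Sex is
coded 0/1; Kendall's τ-b (which assumes no normality) tests the sex
association, Pearson's r the age association.

## Synthetic data: what it emulates and what it does not

`make_template` builds a smooth face-like height field (dome + nasal ridge
+ lip and chin bumps) on a grid whose `x < 0` half — vertices *and*
triangulation — is a bitwise mirror of the `x ≥ 0` half. Template symmetry
is therefore exact to machine precision, and the mirror of the template is
the template itself up to vertex relabelling. A non-symmetric triangulation
would make even a perfect mirror pair disagree at interpolation level
(fractions of a degree in orientation angle), polluting the symmetric-zero
invariant.

`inject_asymmetry` displaces vertices inside a graph-geodesic ball with a
cosine taper, on one side of the face only (a smoothstep ramp over
`radius/4` near the midline prevents a crease at `x = 0`; a region centred
on a midline landmark is offset laterally by half a radius, because a
one-sided asymmetry peaks off the mirror plane). Kinds: displacement along
normals (`normal_bump`, default), tangential shear, and regional rotation.
Landmarks ride the surface via their nearest vertex. iid Gaussian vertex
noise models residual scan roughness.

**Cohort conditions** (`CohortConfig` defaults, chosen once as a realistic
normal population): 50 subjects; one bump per subject with region drawn
uniformly from {nasal tip, nasal bridge, upper lip, chin} — the regions
where normal-population asymmetry concentrates — side uniform left/right,
radius 12 mm; amplitude `max(0, N(1.5, 0.75))` mm, which yields
surface-orientation asymmetries of roughly 5–30°, spanning several
histogram bins as real faces do; vertex noise SD 0.02 mm; a random rigid
pose (≤5°, ≤5 mm) that the alignment stage must remove. Randomizing region
and side keeps the cohort-mean asymmetry map small, which is what a normal
population looks like: individuals are asymmetric, the average face much
less so. With a planted genetic effect, amplitude gains
`effect × (causal genotype code)` mm per subject; genotypes are
`Binomial(2, maf)` with `maf ~ U(0.05, 0.5)` (causal MAF fixed at 0.3),
age uniform on 3–40 years, sex Bernoulli(0.5). All randomness flows from
one seeded generator.

Not emulated: global face-shape variation between individuals (everyone is
a deformed copy of one template), textured/holed/noisy raw scans,
correlated LD structure between SNPs, and population stratification beyond
what the PC test fixtures construct. Passing tests therefore demonstrate
that the *machinery* recovers planted signal under controlled conditions,
not that the scores are heritable or biologically validated on real faces.

## Problem sizes and numerical choices

Default test/verification sizes: template resolution 40 (≈3,300 vertices,
≈2,300 scored after the crop) for the 50-subject scoring cohort; resolution
121 (≈20,000 scored points) where the canonical τ = 20 regime itself is the
quantity of interest; association runs at n = 500 subjects × 2,000 SNPs
with the causal SNP explaining ≈8.4% of trait variance, repeated over 20
seeds. These sizes keep the full verification suite to tens of seconds
while leaving every statistical check comfortably powered.

Ties and degeneracies: coherent regions are ordered by size (largest first,
ties by smallest member index) — the order never affects Ψ; equal-valued
points at a bin edge go to the right bin (half-open convention); a
monomorphic SNP surviving filtering gets `beta = NaN, p = 1` rather than a
crash; p-values are floored at the smallest positive double before BH.

## Known limitations

- Correspondence is one-way TPS + projection; no symmetric or non-rigid ICP
  refinement, so high-curvature regions can slide under large deformations.
- The deformation-angle feature is direction-only and saturates once the
  flow is signal-dominated; its regional mean is monotone in amplitude only
  through the noise-to-signal transition (this is by design — it is the
  magnitude-independent complement of the other features).
- The magnitude feature's histogram range `[0, cohort max]` makes scoring
  a *new* subject against a frozen model fail loudly if their asymmetry
  exceeds the training cohort's maximum; rebuild the model or widen the
  range explicitly in that case.
- PLINK text (.ped/.map) parsing covers biallelic SNPs with `0 0` missing
  codes only; binary .bed is out of scope.
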