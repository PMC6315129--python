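# faceasym

Automated phenotyping of **3D facial asymmetry** from triangulated surface
scans, and quantitative-trait association of the resulting scores with SNP
genotypes.

Human faces are never perfectly symmetric; how much, where, and in what way
a face deviates from its mirror image is a quantitative trait with both
genetic and environmental determinants. Sparse landmark sets miss most of
this signal. `faceasym` scores asymmetry densely: every point of a cohort
average mesh is mapped onto each subject's scan and its midsagittal mirror,
local asymmetry features are computed at all of those points, and a subject
is summarized by how far their feature *map* deviates from the cohort's
model of normal asymmetry — jointly in feature values and in their spatial
layout. The package is aimed at craniofacial morphometrics and imaging-
genetics researchers who need a continuous, automated asymmetry phenotype
for association studies.

## Method

For subject mesh $S$ (rigidly landmark-aligned so the midsagittal plane is
$x=0$) and its mirror $S'$, each point $j$ of the average mesh is mapped to
corresponding points $p_j \in S$, $p'_j \in S'$ by a thin-plate-spline warp
followed by closest-point projection. The **asymmetry flow vector** is
$v_j = p'_j - p_j$, and three local features are derived:

- *angle of surface orientation* $\theta_j = \angle(n_j, n'_j)$ between the
  surface normals at $p_j$ and $p'_j$ (degrees);
- *angle of deformation* $\phi_j = \angle(v_j, n_j)$ (degrees);
- *deformation magnitude* $m_j = \lVert v_j \rVert$ (mm).

A reference cohort defines the **normal model**: per-point mean $\mu_j$ and
SD $\sigma_j$ of each feature. A subject's map $A$ is compared with the
model mean map $A'$ through a **spatially augmented histogram**
$h(b) = \langle n_b, R_b \rangle$: bin $b$ holds its point count $n_b$ and
the coherent regions $R_b$ — connected components of the bin's points on
the mesh graph with at least $\tau$ members. The directed distance

$$d(h,h') = \sum_b \Psi_b \left(1 - \sqrt{p_b\, p'_b}\right),\qquad
\Psi_b = \sum_i \frac{|r_{bi}|}{\sum_i |r_{bi}|} \cdot
\frac{1}{|r_{bi}|} \sum_{j \in r_{bi}} \frac{|A(x_j) - A'(x_j)|}{\sigma_j}$$

weights the per-region mean standardized error by the Bhattacharyya
dissimilarity of the normalized bin frequencies $p_b = n_b/N$, and the
**asymmetry score** is the symmetrized distance
$\rho(h,h') = \tfrac12\,(d(h,h') + d(h',h))$. A score of 0 means the
subject matches the population-average asymmetry pattern exactly.

Two classical baselines are included (mean deformation magnitude over the
face; mirrored-and-realigned mean paired-landmark distance), plus a
from-scratch association stage: minor-allele-carrier filtering, genotype
PCs, per-SNP OLS of the score on `[1, g, age, sex, PC1..PC4]`, and global
Benjamini–Hochberg FDR across phenotypes.

Because real facial-scan cohorts are access-controlled, the package ships a
first-class synthetic generator: exactly mirror-symmetric face-like
templates, controlled one-sided asymmetry injection, and cohort simulation
with a planted causal SNP — every stage of the pipeline is testable against
known ground truth.

## Worked example

```python
import faceasym as fa
from scipy.stats import spearmanr

cfg = fa.CohortConfig(n_subjects=12, seed=4, resolution=30, n_snps=200, effect=0.35)
cohort = fa.simulate_cohort(cfg)
result = fa.score_cohort(cohort.meshes, cohort.landmarks,
                         subject_ids=cohort.subject_ids,
                         base_mesh=cohort.template_mesh,
                         base_landmarks=cohort.template_landmarks)
print(result.scores.round(4).head(6).to_string())
rho = spearmanr(cohort.truth["amplitude"],
                result.scores["surface_orientation_angle"]).statistic
print(f"\nSpearman(amplitude, orientation score) = {rho:.3f}")
```

prints

```
            surface_orientation_angle  deformation_angle  deformation_magnitude  mean_magnitude  landmark_procrustes
subject_id
s0000                          0.0003            16.1047                 1.7288          0.0457               0.0321
s0001                          0.4036            14.5785                 1.1054          0.0392               0.0423
s0002                          0.0000            14.3858                 1.4744          0.0358               0.0404
s0003                          0.3901            15.9230                 1.7942          0.0505               0.0343
s0004                          0.1317            11.1735                 1.4357          0.0439               0.0506
s0005                          3.5790            13.6012                10.2220          0.1684               0.4954

Spearman(amplitude, orientation score) = 0.865
```

The three feature columns are the spatiogram scores (unitless standardized
distances from the normal model; subject `s0005` carries the largest
injected asymmetry and stands out on every dense score), `mean_magnitude`
is the average mirror displacement in mm, and `landmark_procrustes` the
sparse landmark baseline in mm. The injected amplitude is recovered with
rank correlation 0.87 even at this small cohort size.

The same workflow is available from the shell:

```bash
faceasym simulate --out cohort/ --n-subjects 50 --seed 1 --n-snps 2000 --effect 0.35
faceasym score    --cohort cohort/ --out scores.tsv
faceasym assoc    --scores scores.tsv --cohort cohort/ --out assoc.tsv --plot manhattan.png
```

## Documentation

See `docs/methods.md` for the model assumptions, parameter choices, what
the synthetic generator does and does not emulate, and known limitations.
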