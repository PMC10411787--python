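# phalanxgmm

3D geometric morphometrics of reindeer/caribou proximal phalanges: a tested,
reusable implementation of the full ecomorphological workflow that relates
the **size and shape of the proximal first phalanx** to **subspecies,
habitat and mobility pattern** — the kind of analysis used to infer the
migratory behaviour of past reindeer populations from their bones.

It is written for zooarchaeologists and morphometricians who have landmark
data (or want to prototype against realistic synthetic data) and need the
whole chain in one place:

1. **Sliding semilandmarks** — curve semilandmarks slide along their tangent
   vectors and surface semilandmarks within their tangent planes to minimize
   the thin-plate-spline (TPS) bending energy against a reference; each
   sliding step is an exact quadratic minimization, so the energy never
   increases within an iteration.
2. **Generalized Procrustes Analysis (GPA)** — iterative removal of
   position, orientation and size (proper rotations only), yielding
   Procrustes shape coordinates and centroid sizes
   CS = sqrt(Σᵢ ‖xᵢ − x̄‖²), analysed on a log scale.
3. **Shape-space PCA** with TPS warping of the consensus toward the axis
   extremes (default magnification 0.1) for visualizing shape variation.
4. **Size tests** — Kruskal–Wallis per factor, pairwise Wilcoxon rank tests
   with Benjamini–Hochberg correction.
5. **MANOVA with Pillai's trace** V = tr(H(H+E)⁻¹) on PC scores, with the
   standard approximate F: with p responses, hypothesis df q and error df
   nₑ = n − g, s = min(p,q), m = (|p−q|−1)/2, n′ = (nₑ−p−1)/2,
   num df = s(2m+s+1), den df = s(2n′+s+1).  Pairwise contrasts are
   single-df tests against the pooled full-model error, Bonferroni-capped.
6. **Cross-validated CVA** — canonical variate axes from the between- vs
   pooled within-group eigenproblem, leave-one-out Mahalanobis
   classification with equal priors, correct-classification % and Cohen's
   kappa.
7. **Allometry** — multivariate regression of shape on log centroid size,
   %-variance explained and a seeded permutation test.

The number of PCs carried into group statistics never exceeds 95% of
cumulative variance and never the size of the smallest group.

A first-class **synthetic-data module** emulates the study's sampling
design — two limb templates (fore: 4 landmarks + 43 curve + 25 surface
semilandmarks; hind: 4 + 45 + 25), 7 subspecies+habitat+mobility groups
(34 forelimb / 44 hindlimb specimens), group mean-shape offsets, a planted
allometric component (5.90% fore / 2.34% hind of shape variance by
default), sexual size dimorphism with overlap, digitization noise, and a
random similarity transform per specimen — so every stage is testable with
no 3D scans.

## Worked example

Simulate the forelimb design and run the full workflow:

```sh
phalanxgmm run --limb fore --seed 7 --out results/fore
phalanxgmm report results/fore
```

prints (abridged):

```
run complete: 34 specimens, 7 MANOVA terms, 2 CVA factors -> results/fore
== manova ==
     term  Df   Pillai  approx F  num Df  den Df       Pr(>F)  n PCs  n  g
  habitat   2 1.718044 22.632314      14      52 2.852203e-17      7 34  3
 mobility   2 1.442437 11.641680      12      54 4.436127e-11      6 34  3
== cva ==
  factor  PCs   CCV (%)    Kappa  n
 habitat    7 94.117647 0.908108 34
mobility    6 88.235294 0.812672 34
== allometry ==
 % variance (size)  p (permutation)  n  permutations  seed
          5.773131            0.046 34           999     7
```

Reading this: habitat separates the 34 synthetic specimens strongly in
shape space (Pillai 1.72 on 7 PCs, p ≈ 10⁻¹⁷); leave-one-out CVA assigns
94% of specimens to the right habitat (kappa 0.91, far beyond chance); and
5.8% of shape variance is size-related (permutation p = 0.046) — the run
recovers the 5.90% allometric effect planted by the generator.  The run
directory also contains aligned landmarks, PC scores, pairwise Wilcoxon and
MANOVA tables, confusion matrices, and PLY point sets of the consensus
warped to the PC extremes.

The same subcommands work on real data: `simulate`, `slide`, `gpa`, `pca`,
`stats`, `cva`, `allometry`, `run`, `report`, with landmarks in a long CSV
(`specimen_id,point_index,x,y,z`) or the tps dialect, and a metadata CSV
(`specimen_id,subspecies,habitat,mobility,sex,limb[,side]`).

From Python, the estimators compose in the scikit-learn style:

```python
from phalanxgmm import (study_spec, generate_population, slide_semilandmarks,
                        gpa_align, pca_shape, cva_crossvalidated)

ds = generate_population(study_spec("hind", seed=1))
aligned = gpa_align(slide_semilandmarks(ds).configurations)
space = pca_shape(aligned)
report = cva_crossvalidated(space.scores, ds.labels("habitat"), n_pcs=11)
```

## Limitations

Synthetic shapes are statistical stand-ins, not biomechanical phalanx
models; slid semilandmarks are not re-projected onto a surface mesh; and
within-group noise is isotropic, which makes synthetic group separations
easier to classify than real ones (see `docs/methods.md`).
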