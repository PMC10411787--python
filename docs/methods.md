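# Methods

This note documents the models, numerical choices and limitations behind
`phalanxgmm`. It covers what each stage computes, the defaults and why,
what the synthetic generator does and does not emulate, and the open design
choices the package resolved.

## Landmark templates

Each limb's proximal phalanx epiphysis is digitized as a fixed template:
4 anatomical landmarks (crest/cavity extrema), ordered runs of curve
semilandmarks along the articular crests, and two surface-semilandmark
patches covering the lateral and medial articular facets. The forelimb
template has 72 points (4 + 43 + 25), the hindlimb 74 (4 + 45 + 25).
Point indices are 1-based in template definitions (the convention of
anatomical landmark tables) and 0-based internally. Coordinates are
millimetres; no unit conversion is attempted. Left-side specimens, when a
`side` column is present in the metadata, are mirrored (x negated) at
dataset assembly so reflection never enters the Procrustes fit.

## Thin-plate spline and bending energy

The 3D TPS uses the kernel U(r) = −r. The sign is chosen so that the
bending-energy quadratic form — the upper-left k×k block of the inverse of
the bordered system matrix — is positive semi-definite; the interpolating
map itself is identical under either sign. Affine functions of the source
configuration (in particular the source coordinates themselves) lie in the
null space, so the energy is zero exactly on affine images of the
reference, invariant to rigid motions of the target, and strictly positive
for any non-affine displacement. A source configuration with coincident
points (pairwise distance < 1e−9) raises a conditioning error rather than
producing a near-singular solve.

## Sliding semilandmarks

Because the tangential position of a semilandmark along its curve or
within its surface patch is arbitrary, semilandmarks are slid to minimize
the TPS bending energy against a reference. The allowed displacement is
linear in the sliding parameters (one tangent direction per curve point,
two per surface point), and the energy is quadratic, so each sliding step
solves a single linear system exactly — the energy against the current
reference cannot increase, which the tests assert over five iterations.

Estimators (the data do not dictate them, so these are package choices):
curve tangents by central differences along the stored curve order, with
the run's two anchor landmarks closing the ends; surface tangent planes
from the two leading principal directions of the 6 nearest within-patch
neighbours. The default schedule is 3 outer iterations of
(slide → re-superimpose), tolerance 1e−6 on total displacement, sliding
against the recomputed Procrustes consensus; sliding against a fixed
template configuration is available (`reference="template"`). Slid points
are **not** re-projected onto an underlying mesh — a stated limitation:
after large slides the points can leave the (unavailable) true surface.
Slid configurations are returned in each specimen's original frame, so
fixed landmarks keep their input coordinates exactly.

## Generalized Procrustes Analysis

Full GPA: centre, scale to unit centroid size, rotate each configuration
onto the running consensus by orthogonal Procrustes (determinant +1
enforced — reflections are an I/O concern), re-estimate the consensus, and
iterate until the consensus moves < 1e−10 (cap 100 iterations). A partial
fit (`scale=False`) keeps centroid size. The consensus is put into a
canonical orientation — principal axes on the coordinate axes, signs fixed
by the first landmark's octant — so that permuted inputs and global
similarity transforms of the whole sample reproduce identical output
coordinates.

## Shape statistics

* **PCA** on the vectorized aligned coordinates about their mean; null
  dimensions (eigenvalue < 1e−12 of the largest) are dropped and variance
  percentages sum to 100 over the retained ones.
* **PC-count rule**: the largest count whose cumulative variance share does
  not exceed 95%, capped at the smallest group size, never below 1. The
  pipeline additionally caps at n − g so the MANOVA error matrix stays
  full-rank, and records the count used in every result table.
* **Kruskal–Wallis** (tie-corrected, df = g − 1); an all-tied sample is
  reported as H = 0, p = 1 rather than NaN. Pairwise **Wilcoxon rank-sum**
  tests are exact when both groups have ≤ 10 observations and no ties,
  otherwise the normal approximation with continuity correction;
  Benjamini–Hochberg adjustment over the family of all pairs.
* **MANOVA, Pillai's trace** V = tr(H(H+E)⁻¹) with the standard
  approximate F (num df = s·max(p,q), den df = s(nₑ − p + s)). Pairwise
  comparisons are single-df contrasts (q = 1) tested against the pooled
  within-group error of the **full** model, so the denominator df is the
  same for every pair; p-values are Bonferroni-multiplied and capped at 1
  by default (BH selectable). Interaction factors are tested as composite
  cross-classifications: the observed cells act as groups (df = cells − 1);
  a true factorial decomposition is out of scope.
* **CVA**: canonical axes from the symmetric generalized eigenproblem of
  between- vs pooled within-group covariance; classification by nearest
  group mean in canonical space with **equal priors** (group sizes here are
  sampling artifacts, not prevalences), which is equivalent to Mahalanobis
  classification because group-mean differences span the canonical
  subspace. Accuracy is leave-one-out with axes and means refitted per
  fold; reported as correct-classification % and Cohen's kappa
  (κ = (p₀−pₑ)/(1−pₑ), defined as 1 when a degenerate margin has perfect
  agreement).
* **Allometry**: per-coordinate OLS of shape on log centroid size;
  the size share is 100·SS_model/SS_total summed over coordinates;
  significance by permuting log sizes (999 permutations by default, seeded,
  p = (1+exceed)/(1+permutations)); regression scores are projections of
  centred shapes on the fitted direction.

## Synthetic populations

The generator emulates the study's sampling design: per limb, 7
subspecies+habitat+mobility groups with the published sizes (34 forelimb,
44 hindlimb; 24 caribou forelimb) and sex composition. Per specimen it
draws log CS ~ Normal(group mean + sex shift, sd), builds
shape = base + group offset + strength·(logCS − mean)·allometric vector
+ iid Normal(0, noise_sd) per coordinate, then applies a random similarity
transform (scale set so the recorded centroid size equals exp(logCS)
exactly). Effect directions are drawn once per specification from seeded
Gaussians and projected orthogonal to the translation/rotation/scale
tangent directions at the base shape, so planted effects live purely in
shape space. The base shape is a deterministic stylized epiphysis — two
articular paraboloid cups separated by a sagittal groove, crest arcs
between the anchor landmarks — normalized to unit centroid size.

Defaults (`DEFAULT_CALIBRATION`, `OFFSET_SCALE`, `ALLOMETRY_TARGET_PCT`):

| parameter | value | meaning |
|---|---|---|
| `noise_sd` | 0.01 | within-group coordinate noise, shape units |
| `sd_log_cs` | 0.06 | within-group spread of log centroid size |
| `sex_size_shift` | ±0.04 | male/female shift of mean log size (overlapping) |
| `group_offset_scale` | 0.28 fore / 0.30 hind | norm of each group's mean-shape offset |
| planted allometry | 5.90% fore / 2.34% hind | size-related share of shape variance |

Group offsets are drawn mostly within a shared 2-D plane of "ecological"
shape axes plus a smaller idiosyncratic component (`offset_plane_mix` 0.4):
real between-group differences concentrate on few axes, and this is what
lets the leading two PCs of a default run (sliding included) carry roughly
half the shape variance, as in real samples of this kind. The allometric
amplitude is solved analytically from the variance components
(`amplitude_for_planted_pct`) so the planted size share is exact.
`orthogonal_offsets` builds explicitly orthogonal offsets of a prescribed
norm for planting group separations of a known Mahalanobis size.

**What the generator does not emulate.** Within-group variation is
isotropic iid noise, whereas real within-group shape variation is spatially
correlated. Consequences: (i) synthetic group separations large enough to
reproduce realistic PC1+PC2 shares are much easier to classify than real
ones — cross-validated CVA on default runs scores in the 90s rather than
the low 80s; (ii) passing tests demonstrate the correctness of the
machinery and its recovery of planted effects, not classification rates
attainable on real bones. The estimated allometric share also carries the
usual chance-correlation bias of order 1/(n−1) (≈ 2–3 percentage points at
these sample sizes), and sliding — by removing tangential noise variance —
slightly inflates all structured variance shares.

## Problem sizes used in the test suite

Type-I error rates are estimated from 500 null simulations of the forelimb
design (equal group size means, no allometry, no sex shift), with the
permutation test at 199 permutations (exact 5% threshold attainable:
p ≤ 0.05 ⇔ at most 9 exceedances). Allometry recovery uses 200 replicates
per limb with a planted 6% effect. The planted-separation classification
check uses 3 groups × 20 specimens: at smaller groups (12), PC estimation
noise in 216 coordinate dimensions caps leave-one-out accuracy near 89%
regardless of separation (the Marchenko–Pastur spread of sample noise
eigenvalues at n ≪ 3k is comparable to the planted between-group
eigenvalues), so group size — which the separation condition does not fix —
is chosen where the separation, not estimation noise, is limiting. The
whole suite runs in about half a minute on one CPU.

## Known limitations

* No mesh-based resampling or re-projection of slid semilandmarks; no
  curvature-based template building; meshes are optional visualization
  targets only (warps are exported as ASCII PLY point sets).
* The composite-cell reading of interaction terms matches the reported df
  pattern but is not an additive factorial decomposition.
* The PC-count rule is implemented as stated (≤ 95% cumulative, capped by
  the smallest group); analyses that used more PCs than the cap allows
  must pass `n_pcs` explicitly.
* Synthetic shapes are statistical stand-ins for articular surfaces, not
  biomechanical models of the phalanx.
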