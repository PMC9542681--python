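# Methods

## The problem

Flowers with complex (e.g. rotational) symmetry consist of repeated organs
in different positions and orientations. Directional asymmetry (DA) in such
a structure means the repeated parts differ systematically — and more than
one *direction-giving factor* can produce it: anatomical polarity (an
organ's position relative to the flower's bract, here the outer spathe), a
consistent environmental gradient (acting by compass direction, e.g. solar
irradiance), and the inherent left–right asymmetry of each organ (which, if
shared by all organs of a whorl, produces a "pinwheel" pattern). These
effects are only separable if each organ's compass orientation and
spathe-relative orientation are recorded; otherwise they are absorbed into
the estimate of fluctuating asymmetry (FA). `floralsym` implements the
multi-level analysis that separates them, for an *Iris*-like flower with
three falls, three standards and three petaloid style branches whose
orientations are discretized to 60° sectors (0° = south, clockwise).

## Shape quantification

Organs are 2D landmark configurations (18 landmarks for falls and style
branches, 19 for standards; coordinates in mm). Size is centroid size
(root summed squared landmark-to-centroid distances). Shapes are
superimposed by partial generalized Procrustes analysis: translation to
zero centroid, scaling to unit centroid size, least-squares rotation to an
iteratively re-estimated consensus (no extra cosine rescaling), followed
by orthogonal projection onto the tangent space at the consensus — one
common linear space for all downstream statistics. Convergence is declared
when the consensus changes by less than 1e-10 (far below data noise), with
a 100-iteration cap; degenerate (zero-size) configurations are rejected.

## Object-symmetry decomposition

Each organ is internally bilaterally symmetric, described by a pairing
scheme (left/right landmark pairs plus midline landmarks). A
reflected-and-relabeled copy of each configuration (x-coordinates negated,
paired labels swapped — the axis choice is immaterial after
superimposition) is added to the sample and the joint set is superimposed
together. The consensus is symmetrized every iteration and rotated so its
symmetry axis lies exactly on the coordinate y-axis, which makes it an
exact fixed point of reflection-and-relabeling. In tangent space:

* symmetric component = ½ (aligned original + aligned mirror copy),
* asymmetric component = aligned original − symmetric component.

This gives exact additivity; the symmetric part is invariant and the
asymmetric part negates under reflection-and-relabeling. Both copies are
scaled to unit centroid size in the joint fit (a convention; size
asymmetry is not modeled). With p landmark pairs and l midline points the
two components span complementary subspaces whose ranks add to the full
shape-space rank 2k − 4; this is verified empirically in the tests.

## Orientation grouping and inference

The relative orientation of an organ is (compass − spathe) mod 360,
always a multiple of 60 in [0°, 300°]. A flower is classified "expected"
when its falls sit at relative 0/120/240 (one fall directly above the
outer spathe) and "rotated60" at 60/180/300; inconsistent falls are
rejected. Spathe-orientation uniformity is tested with the Pearson
chi-square statistic against equal expected counts (df = 5).

Whole-flower-level DA is tested by comparing organs across orientation
groups (matching symmetry realized as orientation grouping):

* **Centroid size**: classical one-way ANOVA per organ type, with
  group-mean/SE tables. Zero within-group variance yields an infinite F
  with a warning.
* **Shape**: canonical variate analysis and permutation tests on the
  symmetric and asymmetric tangent components separately.

**Goodall's F** is the ratio of between- to within-group mean squared
Procrustes (tangent) distance. **Pillai's trace** is trace(H (H+E)⁻¹) of
the between- (H) and within-group (E) cross-product matrices. Because the
decomposition makes shape components rank-deficient, Pillai is computed on
the principal subspace where the *total* scatter H+E has relative
eigenvalues above 1e-8. Reducing on the total scatter rather than the
within-group scatter keeps the reduction fixed under label permutation and
gives the correct boundary value (Pillai = G−1 for fully separated groups
with no within-group variation); on data whose between-group variation
lies inside the within-group subspace the two reductions agree.

CVA pre-projects the data onto the subspace where the pooled within-group
covariance has relative eigenvalues above 1e-8, whitens the within-group
metric there, and diagonalizes the between-group covariance; at most
min(G−1, within-rank) axes are retained and scores have identity pooled
within-group covariance. Group-mean uncertainty on CV1–CV2 is shown as
95% confidence ellipses from the per-group score covariance scaled by
1/n_g and the 0.95 chi-square quantile with 2 df (a large-sample
convention; an F-based small-sample ellipse would be slightly larger for
small groups).

**Permutation tests** permute group labels with p = (#{perm ≥ obs} + 1) /
(n_perm + 1), 10,000 iterations by default, seeded. The default
exchangeable unit is the organ; a flower-level unit (label blocks shuffled
among flowers with equal organ counts) is provided because organs within a
flower may be correlated. When the number of distinct organ-label
arrangements does not exceed the requested iterations, the organ-level
test enumerates all arrangements exactly and flags the result. Multiple
organs/components are tested without multiplicity correction; callers see
every test reported separately.

## Shape visualization

Mean-shape differences are drawn by warping an outline through the 2D
thin-plate spline interpolant mapping the reference landmarks to
reference + exaggeration × (target − reference); the default exaggeration
is 15, chosen to make subtle floral DA visible. Landmarks interpolate
exactly; an affine shape difference reproduces the affine map (zero
bending energy). Collinear or duplicated reference landmarks make the TPS
kernel singular and are rejected.

## The synthetic-data generator

`SimulationParams.defaults()` emulates the field study's structure:

| parameter | default | meaning |
|---|---|---|
| `n_flowers` | 462 | flowers (three organs per whorl each) |
| `p_expected_alignment` | 315/462 ≈ 0.682 | probability of the ground-plan arrangement |
| `spathe_orientation_weights` | uniform | spathe compass sector distribution |
| `mean_size` (mm) | 350 / 355 / 217 | fall / standard / style-branch centroid size |
| `size_sd` (mm) | 42 / 44 / 26 | between-organ size SD |
| `compass_amplitude` | 0.01 | compass-linked DA field norm (unit-size tangent units) |
| `relative_amplitude` | 0.0 | spathe-relative DA field norm |
| `organ_da_amplitude` | 0.01 | shared per-organ (pinwheel) antisymmetric field norm |
| `fa_sd` | 0.005 | per-coordinate FA SD (unit-size units) |
| `noise_sd` (mm) | 0.5 | per-landmark digitizing error SD |

Templates are bilaterally symmetric petal-like polygons with the study's
landmark counts. Displacement fields are applied in the organ's own frame
at unit size *before* size scaling, so injected effects are commensurate
with tangent-space estimates; digitizing noise is added in mm after
scaling, and each organ receives a random rotation and offset
("scanner-bed pose"). The default compass field combines a symmetric
(elongation/widening, modulated by the sector angle) and an antisymmetric
(shear) part, so a compass gradient moves both shape components, while the
default relative-orientation field is zero and the pinwheel field is a
pure antisymmetric shear — the configuration the analysis is meant to
dissociate. FA draws are isotropic and independent across organs
(within-flower FA correlation is not modeled and would shrink the
effective sample size of organ-level permutation; the flower-level unit is
the robust alternative). Plants carry roughly the study's share of two
flowers per plant. Sizes are drawn independently of orientation — the
study's small (≈2%) size–orientation differences are not emulated.

Effect amplitudes are not printed in the source study, so they were fixed
once by a noncentrality calculation: with per-coordinate shape SD
σ ≈ √(fa_sd² + (noise_sd/mean_size)²) ≈ 0.0052 and N organs split over six
sectors, Goodall's noncentrality is ≈ N·a²/σ², giving ≈ 165 at a = 0.01
with N = 45 — far beyond the ≈ 40 needed for 90% power — while remaining
a subtle (~1% of size) shape effect. What passing tests show is therefore
that the pipeline detects and attributes effects of realistic subtlety
under the stated noise model, not that real digitizing error or real FA
covariance behaves like the model.

## Validation problem sizes

Monte-Carlo checks use 500 replicate datasets of 15 flowers (45 falls,
~7–8 per sector) with 199 permutations per test — enough to place a 5%
rejection rate within ±2% and to populate every orientation sector — and a
single 400-flower dataset (1,200 falls) for pinwheel-field recovery, where
the expected Monte-Carlo error of the mean asymmetric component is ≈ 8% of
the injected field norm (tolerance 20%). Field recovery is assessed
against the injected displacement with its similarity components removed
(rotation and scale overlap are absorbed by superimposition — notably most
of a shear field's norm is a rigid rotation) and re-expressed in the
consensus frame.

## Known limitations

* 2D landmarks and bilateral object symmetry only; no semilandmarks, no
  3D or rotational-symmetry-group Procrustes (whole-flower symmetry is
  handled by orientation grouping).
* Orientations are discrete 60° sectors; no circular statistics.
* Size asymmetry within an organ is not modeled (both joint-fit copies are
  scaled to unit size).
* The chi-square mean-confidence ellipse and the organ-level default
  permutation unit are conventions; both alternatives (F-quantile
  ellipses are not implemented; flower-level permutation is) should be
  considered for strongly clustered data.
* Real-data replication requires user-supplied pairing schemes binding
  each organ's landmark indices, which are not shipped for any published
  landmark set.
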