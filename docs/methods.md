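# Methods

This note documents the models, conventions and numerical choices behind
`strokemap`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Behavioral scoring

All geometry is in millimetres; the signed convention is positive =
left-lateralized deficit (a rightward bias on the page or object).

**Centre of cancellation.** The raw CoC is the mean horizontal position of
the *marked* full targets divided by the page half-width, so it always lies
in [−1, 1]. It is sign-mapped so that positive means a contralesional
omission bias (for a right lesion, marks clustering on the right = left-side
omissions), then z-transformed against a configurable normative mean/SD
(default 0/1; no normative sample ships with the package). The assembled
score vector re-expresses it in the page convention, which makes it
independent of lesion side when the normative mean is 0.

**Allocentric score.** *A* = (Contra_err − Ipsi_err)/Whole_corr, where the
contralesional category of opened-apple distractors is `left_open` for right
lesions and `right_open` for left lesions, and Whole_corr is the number of
correctly marked full targets. *A* is antisymmetric under swapping the two
error counts and bounded by (Contra_err + Ipsi_err)/Whole_corr.

**Clock asymmetry.** Correct hour *h* sits at 30°·*h* clockwise from
12 o'clock. Hours 1–5 are right-lateral, 7–11 left-lateral, 12 and 6
midline. Per side: 1 point for each omitted lateral hour; 1 point for each
lateral hour drawn across the vertical midline (credited to its correct
side); 0.5 point for a within-side displacement beyond a 30°-total cone
(±15°) centred on the correct location. A midline hour displaced beyond the
cone into a lateral half scores 1 point for the side it moved *away* from
(a rightward shift of "12" indicates a left-side deficit). Omitted midline
hours carry no lateralized information and score nothing. This rule set
makes the score exactly antisymmetric under left-right mirroring of the
drawing, which the tests verify.

**Clock margin.** Margin per side = circle radius − max |x| over the
placements in that half (x = r·sin θ); the score is left margin − right
margin. Hours drawn outside the circle produce negative margins and are
accepted.

**Construction.** MoCA cube/chair (0–1) and clock (0–3) points are inverted
(1−raw, 3−raw) so that 0 = intact.

## Factor decomposition

PCA is an eigen-decomposition of the 8×8 correlation matrix of the
column-standardized (sample SD, ddof = 1) scores; variance explained per
component is 100·λᵢ/8 and is reported from the *unrotated* eigenvalues
(rotated sums of squares are exposed separately). Components are retained by
the Kaiser rule (λ > 1), with an explicit override. Rotation is direct
oblimin at δ = 0 (quartimin) via the standard oblique gradient-projection
algorithm (step-halving line search, criterion tolerance 1e-8, iteration cap
1000), with Kaiser row normalization before and de-normalization after.
Rotated factors are deterministically oriented (largest |loading| positive)
and ordered by explained sum of squares. Factor scores use the regression
method, B = R⁻¹ΛΦ on standardized data; for the complete unrotated model
these reproduce the data exactly (scores·Λᵀ = Z). The rotation preserves
ΛΦΛᵀ and communalities by construction, which the tests check to 1e-8
together with recovery of an exactly simple structure.

## Lesion quantification

World x > 0 is the right hemisphere. Mirror flipping reflects lesioned
voxels through the world plane x = 0 with nearest-neighbour re-gridding and
refuses affines that shear across x; on the centred grids the generator
produces, the flip is an exact voxel permutation (volume-preserving,
involutive). The pipeline always flips left-lesioned patients before any
damage computation. Parcel damage is 100·|lesion ∩ parcel|/|parcel|. A
streamline is disconnected as soon as any voxel on its path is lesioned;
tract and edge disconnection are the percentage of interrupted streamlines
per tract and per unordered endpoint-parcel pair. The coverage rule excludes
features damaged in fewer than 10% of patients; exactly 10% is retained.

## SVR lesion-symptom mapping

Order of operations per component: coverage mask → lesion-volume regression
(default mode `both`: volume is residualized out of the behavior *and* every
feature column) → nuisance regression of behavior on age, gender and days
post-stroke (intercept included) → SVR fit → permutation inference.

The feature matrix is globally scaled to unit mean squared row norm before
the kernel is formed. This single scalar keeps the Gram matrix O(1) whether
features are binary voxels or 0–100 percentages (the SMO solver stalls by
orders of magnitude on badly scaled kernels, and the RBF γ is only
meaningful on normalized vectors) and does not change the direction of the
weight vector. The target is z-scored before each fit so that epsilon is in
SD units of the behavior. Defaults: linear kernel, C = 1, ε = 0.1; an RBF
kernel (γ = 5, sensitivity-map back-projection) is available behind a flag.
C = 1 on the normalized kernel was chosen because a weakly regularized fit
(large C) at n ≈ p is nearly interpolating: the weight vector spreads over
collinear features and planted-truth recovery collapses, while C ≈ 1 gives
covariance-map-like behavior with intact attribution. The linear-kernel β
equals Σᵢ αᵢxᵢ scaled to unit Euclidean norm.

**Permutation inference.** The adjusted behavior vector is permuted
(residual permutation; covariates are not re-permuted) and the SVR refitted,
reusing the cached kernel. One-tailed per-feature
p = (1 + #{permuted β ≥ observed β})/(n_perm + 1); identical seeds give
bitwise-identical maps. For parcel/tract/edge maps, FWE correction uses the
*studentized* β: each feature's β is centred and scaled by its own
permutation-null mean and SD (the permutation analogue of a corrected
z-map), and corrected p is the exceedance of the observed z under the null
distribution of the per-permutation *maximum* z. Raw-β maxima are dominated
by frequently lesioned features whose null β varies most, which destroys
power at heterogeneous lesion frequencies; studentizing equalizes the null
scale and leaves the per-feature p (a within-feature rank) unchanged.

**Cluster-extent correction (voxel level).** Voxels with permutation
p < 0.005 (one-tailed) are grouped by 26-connectivity (configurable 6/18/26);
each permutation's own map is thresholded identically — the permutation's
own value plays the observed value's "+1" role in its p, so permutation maps
live on the same p scale as the observed map — and contributes its maximal
cluster size to the null; cluster p = (1 + #{null max size ≥ observed
size})/(n_perm + 1), with survival at p < 0.05. Note that the forming
threshold needs n_perm ≥ 1/0.005 − 1 = 199 permutations to be attainable at
all; the standard setting is 5000, the validation experiments use 500.

## Synthetic cohort

The generator emulates a two-phase stroke cohort at study scale: 77 patients
by default (40 acute, 49 right-hemisphere), a 40×48×40 grid at 2 mm with
voxel centres symmetric about every world axis. The atlas has 60 cuboid
parcels per hemisphere (five anteroposterior bands × four heights × three
depths, ≈3 cm³ each — comparable to connectome-atlas granularity), exactly
mirror-symmetric, with 8-streamline bundles for two longitudinal tracts per
hemisphere and two homotopic callosal-like bundles. Lesions are region-grown
random blobs confined to one hemisphere, with volumes log-uniform over
2000–12000 voxels (16–96 cm³): right-skewed, in the range of the large
middle-cerebral-artery strokes that produce visuospatial deficits, and large
enough relative to the parcels that per-parcel damage carries signal.

Scores are linear in damage plus Gaussian noise (Laplace behind a flag):
each planted effect adds weight · scale(score) · damage%/100, and every
score receives noise SD = noise_sd · scale(score). The per-score scale maps
a single dimensionless weight/noise pair into each test's native units
(z units for CoC, mm for bisection and margin, points for the clock and MoCA
scores) while keeping every score inside the range a raw response can
physically represent. The default effect structure plants three blocks —
cancellation/long-bisection on a frontal parcel, construction/short-bisection
on a temporoparietal parcel, clock scores on a dorsal tract — reproducing a
three-component factor solution.

Raw-response generation inverts the scoring rules: cancellation marks are
placed so the marked-target mean reproduces the CoC exactly and the
distractor-error difference reproduces the allocentric numerator exactly;
bisection marks are placed at the target deviation; clock omissions,
translocations and radial placements realize the asymmetry (quantized to
0.5) and margin; MoCA points are rounded and clipped to their ranges.
Continuous scores round-trip within ±0.02 in native units; discrete scores
reproduce their quantized targets exactly.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: anatomically realistic lesion shapes or vascular
territories, curved tractography and partial disconnection, spatial
normalization error, correlated measurement noise across tests, floor and
ceiling effects in severely impaired patients, and any systematic
acute-versus-chronic difference (phase labels are exchangeable by default;
the planted effects are phase-independent unless configured otherwise).

## Validation experiments

`strokemap.validation` runs four planted-truth experiments (problem sizes
chosen to characterize the estimator at desk scale):

- **SVR/OLS equivalence** — noiseless linear target, n = 60, 5 informative
  of 200 binary features; cosine between the SVR β and the minimum-norm
  OLS-with-intercept oracle (pinv on centred predictors, rcond 1e-10)
  exceeds 0.99.
- **Null calibration** — 20 cohorts with no planted effect, n = 60, parcel
  level, 500 permutations: runs with any FWE survivor stay within the
  nominal 5% rate.
- **Recovery** — 20 cohorts, one seeded parcel (a central temporoparietal
  parcel, weight 2, noise SD 0.5), n = 60: the seeded parcel is the top
  |β| feature and survives FWE in the large majority of runs.
- **Planted voxel cluster** — a 40-voxel region drives the score; the
  surviving cluster overlaps it under voxel p < 0.005 / cluster p < 0.05.

## Known limitations

- The oblimin implementation handles δ = 0 only (quartimin), the
  conventional "oblimin" default.
- Streamline disconnection is voxel-path membership; no arc-length
  interpolation or partial-disconnection weighting.
- The RBF back-projection (mean gradient at training points) is a
  sensitivity heuristic; the linear kernel is the analysis default.
- Exact Mann-Whitney p values are used only for tie-free samples with
  n ≤ 20; otherwise the tie-corrected normal approximation applies.
- Single-feature attribution at FWE level degrades when lesions are huge
  relative to parcels (collinear damage columns); this is a resolution limit
  of lesion-symptom mapping itself, not of the implementation.
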