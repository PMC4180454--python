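# Methods

This note records the models, algorithmic choices, parameter defaults, and
known limitations of `lvshape`, in the order the pipeline runs them.

## Coordinate conventions

All geometry is in physical millimetres with RAS axes (+x right, +y
anterior, +z superior); voxel indices are 0-based and the NIfTI affine maps
index → mm. Ages are stored in days everywhere; months (30.4375 days)
appear only in growth rates. Mirroring "right to left" means x → −x in mm.

## Synthetic cohort generator

Each ventricle is a curved tube: a circular arc of total bend 2 rad lying in
a parasagittal plane (|x| = 10 mm), radius profile r(s) over normalized arc
position s ∈ [0,1] (anterior tip s = 0), and an elliptical cross-section
whose left–right semi-axis is `cross_section_ratio` (default 0.75) times the
in-plane one. The flattened cross-section mirrors the real structure's
shape and — importantly for correspondence — makes the first-order
ellipsoid's three axes distinct, so the canonical alignment frame is well
determined; with a circular cross-section the 2nd/3rd axes are ambiguous
and alignment correctly refuses.

Growth is quadratic in age with vertex at `peak_age`:
q(a) = max(0, 1 − ((a − peak_age)/peak_age)²), so q(0) = 0 and q(peak) = 1.
Length scales as 1 + A_len·q (A_len = 0.32) with an anterior-weighted local
density (ramp 1.6 − 1.2 s, mean 1); the radius as 1 + A_rad·q·w(s)
(A_rad = 0.36) with a posterior ramp w(s) = 0.4 + 1.2 s (mean 1). With
peak_age = 450 d these defaults give an analytic year-one volume change of
about +123 % and a year-two change of about −25 %, i.e. the reported
biphasic infant trajectory (left ≈ +126 %, ≈ −24 %), with the observed peak
at the 12-month visit. The quadratic form is deliberately conjugate to the
Age + Age² fixed effects of the statistical models.

Other defaults, chosen once: baseline length 40 ± 3 mm between subjects;
growth amplitudes vary ±20 % (relative SD) between subjects; peak_age
450 ± 30 d; left/right uniform scale asymmetry 1.05 ± 0.02 (volume ratio
≈ 1.16, left larger — present but modest, as in infancy); gender effect a
0.8 mm Gaussian radius bump on the anterior 20 % of the *left* side for
males; boundary jitter `noise_sd` = 0.25 mm as a smooth, zero-mean random
field along the arc, independent per visit and side (roughly a quarter
voxel — deliberately conservative relative to the near-perfect test–retest
overlap such segmentations show). Visits follow the infant schedule
{14, 91, 182, 274, 365, 548, 730} days with 12 % missed visits (a missed
appointment drops both sides); masks are voxelized at 1 mm isotropic on a
grid symmetric about x = 0, so mirroring is voxel-exact. All randomness
flows from declared seeds; regenerating with the same configuration is
bit-for-bit identical. Posterior horns are not generated (the upstream
protocol removes them). A self-intersecting configuration (tube radius
reaching the bend radius) is an explicit error.

The truth table stores every subject's parameters, from which analytic
volumes (Pappus: V = π·c·∫ r(s)² dl) and — see Morphometry below —
predicted band profiles can be evaluated at any age.

The module also contains direct *panel* simulators
(`simulate_volume_panel`, `simulate_profile_panel`, `simulate_shape_panel`)
that draw from the statistical models themselves, for estimator calibration
at exactly known coefficients and variances.

## Mask regularization and meshing

`regularize` keeps the largest 6-connected component (6 for foreground / 26
for background — the standard compatible pair), fills interior cavities,
and repairs the voxel set to be *well-composed* by monotone filling of the
critical 2×2 checkerboard and 2×2×2 corner-pair configurations. The
boundary of a well-composed set is a closed 2-manifold, so the surface is
extracted *cuberille*-style: one quad (two triangles) per
foreground/background 6-neighbour face, vertices on voxel corners, outward
orientation. The enclosed mesh volume then equals voxel count × voxel
volume exactly. A single morphological closing-then-opening with a
1-voxel 6-connected element is applied only if the surface is not genus 0
without it; a surface that still has genus > 0 raises an error naming the
Euler characteristic. Regularization is idempotent.

Marching-cubes meshing was rejected: at 0.5 level it shaves corners (a
single voxel yields 1/6 of its volume), which breaks the volume-fidelity
contract for thin structures.

## Spherical parameterization

Initialization solves two Laplace problems on the mesh graph (uniform
weights): a colatitude field with poles fixed at the extremal vertices of
the first principal axis, with harmonic levels redistributed so the surface
area above each latitude matches the spherical-cap area fraction
F(θ) = (1 − cos θ)/2; and a longitude field obtained by cutting the mesh
along a shortest pole-to-pole path and solving a Dirichlet problem with
boundary values 0/2π on the two sides of the cut (the side assignment walks
the oriented face fan around each cut vertex).

Refinement is projected gradient descent on the KL-type area energy
E = Σ_f τ_f log(τ_f / α_f), where τ_f is the face's share of surface area
and α_f its share of (Euclidean) sphere-triangle area. The KL form has an
infinite barrier against collapsing triangles, which plain quadratic area
energies lack. Steps are normalized so the fastest vertex moves by the
current step length (backtracking line search, growth 1.3×, cap 0.25);
folded spherical triangles are untangled by local Laplacian smoothing, and
the best fold-free iterate is retained. Termination: energy stagnation
(relative improvement < 1e-6 for 30 iterations) or the iteration cap
(library default 10 000; the pipeline uses 600–800, which our profiling
shows reaches median per-face distortion ratios of 1.05–1.15 on 1 mm
ventricle masks in ~2 s per surface). Remaining folded triangles after the
cap are a hard error with diagnostics. Signed spherical-triangle areas (van
Oosterom–Strackee) sum to exactly 4π for a valid covering and are used for
all distortion statistics.

Two caveats, verified by the test suite: (i) the map is area-preserving,
not conformal, so a sphere maps to itself with < 1 % area distortion but a
residual within-latitude shear (the degree-1 fit of a parameterized unit
sphere is a unit sphere, while its pointwise residual is only ~0.07); and
(ii) an equal-area map is unique only up to area-preserving
re-parameterizations, so re-running the pipeline on a rotated copy of a
mask reproduces the aligned point set to about 5 % of the object scale, not
exactly — the first-order-ellipsoid frame is what pins the map down.

## SPHARM fitting and correspondence

Coordinates are fitted by least squares in the real orthonormal spherical
harmonic basis (m = 0: Re Y; ±m: √2(−1)^m Re/Im Y), so the degree-1
functions are exactly proportional to (u_y, u_z, u_x). Default degree
L = 12 ((L+1)² = 169 coefficients per coordinate); fitting requires at
least that many vertices. Degree 0 is permitted and reproduces the
centroid.

The degree-1 block is a linear map M of the parameter sphere; its SVD gives
the first-order ellipsoid (axes = left singular vectors, semi-lengths =
singular values, parameter directions = right singular vectors). Alignment:
(1) the parameter sphere of each surface is rotated so the long-axis
parameter direction goes to the poles (north = anterior, resolved by the
configured anatomical anterior axis, default +y) and the second axis to the
φ = 0 meridian (sign from the superior axis); the rotation is applied by
refitting on a dense icosahedral grid, which is exact for band-limited
functions. (2) rigid Procrustes (Kabsch, rotation + translation, **no
scaling** — growth is the signal) of the sampled point sets onto the first
surface. Surfaces whose 1st/2nd or 2nd/3rd semi-lengths agree within 2 %
(relative to the largest) are rejected as ambiguous rather than silently
assigned a frame. Right-side masks are mirrored (x → −x) *before*
parameterization so left and flipped-right surfaces share one
correspondence.

The PDM samples the series at a frequency-n icosahedral grid
(N = 10 n² + 2; default n = 10, N = 1002). Morphometry uses a denser
sampling (n = 36, N = 12 962) of the *same* coefficients so that 100
colatitude bands are all populated; the vertex-wise statistics stay at
n = 10.

## Mean-latitude-axis morphometry

Sample sites are partitioned into n_bands = 100 equal-width colatitude
bands (matching profile points 1…99 between the anterior and posterior
tips); the medial point is the band's arithmetic mean; local length is the
Euclidean distance between neighbouring medial points; radius the mean
distance from the medial point to the band's sites. Cross-sectional area
is, by default, the area of the band's contour polygon (sites ordered by
longitude) projected onto the plane orthogonal to the local tangent
(central differences of medial points); the π r² alternative is a config
option for sensitivity checks. Empty bands are an error that names the
remedy (fewer bands or higher subdivision).

Interpretation caveat: because colatitude is allocated by *area*, band
boundaries shift when growth is spatially non-uniform, so per-band changes
mix true local growth with correspondence drift, and localized contrasts
(e.g. posterior-minus-anterior radius growth) are attenuated under boundary
jitter. `GrowthTruth.predicted_band_profiles` evaluates the generator's
geometry in exactly these cumulative-area band coordinates, so measured
profile changes are always compared against what the representation
*should* measure, not against the raw arc-position truth. In the
end-to-end acceptance run the posterior-dominance check is therefore made
on cross-sectional area (the better-conditioned quantity) with the radius
and area band-change profiles additionally required to correlate with their
truth predictions.

## Mixed-model engine

Every longitudinal model in the package is a subject-random-intercept LMM
with a design shared across response channels, fitted independently per
channel by maximum likelihood. The profile likelihood depends on one ratio
λ = σ_b²/σ_e² per channel; for fixed λ, GLS gives β and σ_e² in closed form
(Woodbury block inverses), and λ is maximized by golden-section search on
log λ ∈ [−12, 10], *batched across all channels* — this is what makes
1002-vertex maps and 200–500-replicate calibrations cheap (a 1000-column
fit takes ~0.2 s). The fit matches statsmodels MixedLM (ML) to ~1e-6 on
shared cases. ML (not REML) is used everywhere so Wald statistics are
comparable across models; Wald tests use the normal/χ² reference, as lme4
does by default. Zero-variance channels are flagged invalid and excluded
from FDR families.

Because random intercepts and residuals are independent across sides
(volume model) and across directions (shape model) and the fixed effects
are channel-specific, the *joint* ML factorizes into per-channel fits; the
side contrasts β3–β5 and their standard errors are assembled exactly from
the two per-side fits, and the direction-agnostic shape test is the sum of
the per-direction Wald χ² (df 3 × contrast size). No cross-channel
covariance parameter is included — the model states none.

Normalizations (recorded in every fit object): age mapped affinely to
[0, 1] over the observed range; volume z-scored (coefficients are mapped
back to the input scale for reporting); W centered per vertex and
direction. Missing visits are handled by likelihood on available rows; no
imputation.

## Functional (per-band) model and global test

Per band: intercept + piecewise-linear age basis (one slope per
inter-visit interval, knots at the nominal visit ages) + random intercept;
regional tests are per-band per-interval Wald tests. The global test per
measure is the supremum over bands of the joint Wald statistic of the age
slopes computed from the *within-subject* (subject-demeaned OLS)
estimator, calibrated by permuting observed ages within subject (999
permutations; exchangeable under the null given a random intercept and iid
errors). The within-subject statistic was chosen because it is exact to
permute and cheap enough to calibrate at 200 Monte-Carlo replicates; the
measured size is ~0.045 at α = 0.05. Bands with degenerate (constant)
values are skipped and flagged.

## Growth fields

Per vertex, displacements d = x(later visit) − x(first visit) are stacked
over subjects and later visits (consecutive-interval differencing is
available behind a flag) and decomposed by SVD *without centering* — the
mean displacement is the growth signal; centering would estimate dispersion
instead. The principal direction's sign makes the mean projection
nonnegative; the growth rate is the mean projection per month
(30.4375 d). Glyph rendering scales a small icosphere by the singular
values, oriented along the right singular vectors, colored by rate. "Horn"
vertices for summaries are the polar 15 % of colatitude at either end.

## Pipeline, seeding, problem sizes

One global seed fans out to per-stage seeds via
`numpy.random.SeedSequence(seed).spawn`; the manifest records config, stage
seeds, and SHA-256 of every artifact, and each stage re-runs from cached
upstream artifacts. Default study conditions are 24 subjects × 7 visits ×
2 sides at 1 mm. The acceptance script runs its statistical calibrations at
the full stated sizes (200 recovery / 500 size replicates; 200 × 999
permutation replicates) and the imaging end-to-end pass on a 16-subject
cohort — the patterns it checks are signs, orderings, locations, and
truth-correlations, which are stable at that size — finishing in roughly
seven minutes on one CPU.

## Known limitations

* Full functional mixed-effects estimation (functional random effects,
  smoothed coefficient functions) is not implemented; the per-band LMM +
  permutation sup-Wald stand-in preserves the regional/global inference
  structure but is not equivalent to it.
* The equal-area parameterization leaves residual distortion concentrated
  at the tube tips (max per-face ratios can be large there even when the
  median is ~1.05), and rotation invariance of the full pipeline holds only
  to ~5 % of object scale (see above).
* Mean-latitude band profiles conflate local growth with band drift under
  non-uniform growth; localized radius contrasts are conservative.
* Vertex-wise models are fitted independently (no spatial covariance), so
  FDR maps inherit the usual per-vertex power limitations.
* The generator produces binary masks directly; it does not emulate MR
  intensities, tissue segmentation, or posterior-horn anatomy.
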