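# Methods

This note documents the models implemented in twibio, the parameter
choices that matter, what the synthetic phantoms do and do not emulate,
and the numerical decisions a maintainer should know about.

## Track-weighted maps

A track-weighted image summarises a tractogram on a voxel grid: voxel v
holds the mean of a whole-track scalar over the streamlines that traverse
v, together with the count of such streamlines. Two statistics are
provided.

**Pathlength.** A streamline's pathlength is the sum of its Euclidean
segment lengths; a single-point streamline has length 0. The per-voxel
value is the mean *whole-track* length of the tracks passing through the
voxel (not the length of the portion inside the voxel), so a voxel in the
middle of a long bundle reports the full bundle length.

**Mean curvature.** Discrete curvature at an interior point is the Menger
curvature — the reciprocal circumradius of the point and its two
neighbours, κ = 4·Area/(a·b·c). This estimator is exact for concyclic
points (any sampling of a circle of radius r gives exactly 1/r), which is
what makes the analytic phantom tests sharp. A track's curvature is the
unweighted mean over interior points; an arc-length-weighted mean is
available behind a flag (`arclength_weighted=True`) but is not the
default, because uniform sampling makes the two agree and no convention is
canonical. Degenerate triples (a zero-length side) contribute κ = 0;
streamlines with fewer than 3 points have undefined curvature, are
excluded from curvature maps, but still contribute to pathlength maps.

**Voxel membership.** Streamline-to-voxel assignment is exact, not
sampled: voxel cells are half-open boxes [c−0.5, c+0.5)³ in continuous
voxel coordinates, and each segment's crossings of the half-integer planes
are enumerated (grid-walking in the style of Amanatides–Woo); the cell of
each sub-interval midpoint is recorded. A point exactly on a cell's upper
face belongs to the next voxel (half-open convention); a segment lying
exactly in a face plane contributes both adjacent voxels — both rules
exist to make results deterministic under floating point, not to encode a
geometric preference. A track counts once per voxel however often it
re-enters. Map construction is therefore independent of streamline order
up to floating-point summation order (verified to 1e−12).

**ROI medians.** The map is undefined where no track passes; stored maps
hold value 0 / count 0 there, but ROI medians exclude zero-count voxels by
default (`include_empty` reverses this). Including structural zeros would
let ROI coverage rather than geometry drive the median. ROIs with no
traversed voxel report a missing value, never 0. Medians of even-sized
samples are the mean of the two central values.

## Diffusion tensor fit and metrics

The tensor is estimated per voxel from the monoexponential model
S = S₀·exp(−b gᵀDg). S₀ is the geometric mean of the b0 volumes; the six
tensor components solve the log-linearised system over the
diffusion-weighted rows by ordinary least squares. S²-weighted least
squares (the conventional heteroscedasticity correction for log-transformed
Rician/Gaussian magnitude noise) is available via `weighted=True`; OLS is
the default because it is the simplest published estimator and the
reference recovery tests are exact for it. Voxels containing any
non-positive signal are flagged, counted and zeroed rather than producing
NaNs. Negative eigenvalues from noisy fits are *kept* — clamping would
bias the recovery statistics the tests measure — but the count is the
caller's to inspect.

Scalar metrics follow the standard definitions (AD = λ₁, RD = (λ₂+λ₃)/2,
TR = Σλᵢ, FA as the normalised eigenvalue dispersion); FA of an all-zero
tensor is defined as 0. The acquisition scheme used throughout the tests
and phantoms matches the study protocol: b = 1200 s/mm² in 81 directions
plus 8 b0 images; the directions are a deterministic golden-spiral set,
which is non-collinear and well-conditioned but not the scanner's actual
table (which is unpublished).

## RPPM quantification

Fitting happens in log-log coordinates: x = log₁₀(relative concentration),
with dilution step k of a 1:1 series at x = −k·log₁₀2 and the undiluted
print at x = 0; y = log₁₀(net fluorescence). The five-parameter logistic

y(x) = D + (A−D)/(1 + 10^{B(x_mid−x)})^G,  A > D, B > 0, G > 0

is the standard asymmetric dose–response for this assay. Stages:

1. **Preprocessing.** Net = foreground − background; replicate depositions
   at the same (sample, block, dilution) are averaged first; spots with
   SNR < 2 or net < 10 are excluded as indiscernible from background.
2. **Master fit.** Plain nonlinear least squares of the 5PL to all
   included spots of the slide, initialised from the data (A₀ = max y,
   D₀ = min y, x_mid₀ = median x, B₀ = G₀ = 1) with a few deterministic
   perturbed restarts. Tolerances are set tight (1e−15 with Jacobian
   scaling) because the (A, G, x_mid) profile is a shallow valley in which
   looser tolerances stall visibly far from the optimum.
3. **Outlier removal (ROUT-style).** Robust residual scale
   RSDR = P₆₈.₂₇(|residual|)·N/(N−K) with K = 5; per-spot t = |r|/RSDR and
   two-sided p from the t distribution with N−K df; Benjamini–Hochberg at
   Q = 0.01 flags outliers; the master curve is refit on the remainder
   (and is identical to the initial fit when nothing is flagged). The
   final refit is plain least squares, not a fully robust fit — a robust
   final fit can be requested but is not default.
4. **Per-sample fits.** A, D, B, G are frozen at the refined master
   values; only x_mid is fitted per sample. The 1-D profile is solved by a
   dense vectorised grid (±4 decades, step 0.005) followed by bounded
   scalar minimisation to 1e−13 — a single Levenberg–Marquardt start can
   stall on the shallow profile. Samples with fewer than 3 included spots
   are skipped with a warning row.
5. **Quantification.** The 5PL slope dy/dx = (A−D)·G·B·ln10·u/(1+u)^{G+1}
   (u = 10^{B(x_mid−x)}) is maximal at u\* = 1/G, i.e.
   x\* = x_mid + log₁₀(G)/B, where slope\* = (A−D)·B·ln10·(1+1/G)^{−(G+1)}
   and y(x\*) = D + (A−D)(1+1/G)^{−G}. The reported y-intercept is the
   tangent at x\* extended to x = 0, in log₁₀ fluorescence units (the
   units choice is a documented convention; only differences between
   samples are interpretable). Two samples sharing the shape and differing
   in x_mid by Δ differ in y-intercept by exactly slope\*·Δ.

A consequence worth knowing: the master curve is fit to the pooled
dilution series of all samples, so its residual scale reflects the
*between-sample abundance spread*. A single sample whose abundance differs
several-fold from all others produces systematic residuals that the
FDR step will flag wholesale. Balanced designs (comparable group sizes)
keep the robust scale honest; this is a property of the published
procedure, not an implementation artifact.

## Group statistics

The default test is the Student pooled-variance independent t-test with
df = n₁ + n₂ − 2 (Welch–Satterthwaite available via `variant="welch"`),
two-sided p through the regularized incomplete beta function, and
mean ± SEM summaries with the n−1 standard deviation. No multiplicity
correction is applied by default; a Benjamini–Hochberg q-value column is
optional in batch comparisons. p-values compared against printed tables
are rounded half-away-from-zero to 3 decimals, matching how statistics
packages print.

Several published (t, p) pairs convert exactly under Student-t at the
cohort-implied df; a handful do not (plausibly undocumented exclusions or
Welch df in the source analyses), and only the exactly-consistent pairs
are used as reproduction anchors.

## Synthetic phantoms

The generators produce every input the analysis stages consume, with
ground truth attached, so the whole pipeline is testable without any
acquisition. All randomness derives from a master seed through
`SeedSequence` streams keyed by stable (subject, stage) identifiers
(strings hashed by CRC32), so identical seeds give bit-identical data and
different subjects get independent streams.

**Bundles.** Parametric centerlines (straight / circular arc / helix) are
copied with rigid offsets drawn in a disc perpendicular to the bundle axis
— rigid translation preserves the analytic length and curvature exactly —
then perturbed by point jitter. The jitter is marginally Gaussian
N(0, sd²) per point but *smooth along the track* (white noise convolved
with a Gaussian kernel, correlation length 1.5 mm by default, renormalised
to the target sd). Independent per-point jitter would be an unphysical
noise model for tractography — tracking noise is smooth at the step scale
— and would add spurious Menger curvature of order sd/ℓ² (ℓ = segment
length), an order of magnitude above the geometric signal at realistic
sizes. With smooth jitter the mean bundle curvature stays within a few
percent of the analytic truth at sd = 0.05 mm.

**Cohorts.** Four ROI label blocks (ipsilateral/contralateral cortex,
corpus callosum and hippocampus analogues) sit on a common 40×40×8 grid of
0.5 mm voxels; each carries an arc bundle (nominal length 8 mm, curvature
0.25 mm⁻¹, 30 streamlines of 30 points). Injured subjects' ipsilateral
bundles are shortened by `effect_truncation` (default 0.2, the direction
and rough size of the reported pathlength effect) and their curvature
multiplied by `effect_straightening`; the contralateral bundle is drawn
from a stream keyed without the group label, so matched sham/injured
subjects carry *identical* contralateral bundles and the injury is a pure
transformation. Per-subject biological variability is a multiplicative
Gaussian factor (sd 0.03) on length and curvature plus 0.1 mm point
jitter. These defaults were chosen once as a realistic-but-idealised
regime; the phantom does not emulate brain geometry, crossing fibres,
premature tracking termination, or registration error — so passing tests
demonstrate correctness of the *measurement chain*, not robustness to
real-data confounds.

**DWI.** S = S₀·exp(−b gᵀDg) with additive Gaussian noise in signal units.
Gaussian rather than Rician noise is the default so recovery statistics
stay analytic; at the SNR used (≥100) the distinction is negligible.

**Plates.** Spots are generated from a known 5PL shape (defaults A = 4.7,
D = 2.2, B = 1, G = 1.5, x_mid = −2 in log₁₀ units) over 16 dilution
steps × 8 samples, with σ = 0.02 log₁₀ noise, matching a high-quality
slide. The lower asymptote is placed well above the net-fluorescence
detection floor so that ±1-decade gross outliers remain detectable spots —
otherwise the SNR/net preprocessing filter, not the FDR step, would absorb
the down-displaced half. The SNR column is net over a fixed scanner noise
floor, so the SNR < 2 rule engages exactly when a real dim spot would.
Samples default to equal true abundance: the master curve then estimates
the shared shape directly, which is the regime the shape-recovery check
addresses. Recovery of the asymmetry parameter G under these conditions
has a sampling CV of roughly 7%, so the 5%-recovery check is a fixed-seed
(default generator seed) verification, not a uniform-over-seeds guarantee;
the location and asymptote parameters recover one to two orders of
magnitude more tightly.

## Numerical conventions and degenerate inputs

* Voxel indices are 0-based with voxel centers at integer indices (NIfTI
  affine convention); RPPM block ids are 1-based (plate convention).
* TCK I/O round-trips the float32 coordinate payload bit-exactly;
  truncated files and non-Float32LE payloads are rejected, not coerced.
* Masks must be integer-valued; non-integer label volumes are rejected.
* All-zero tensors yield FA = 0; empty ROIs (absent label, or no eligible
  voxel after count filtering) raise rather than return 0.
* Two zero-variance groups with equal means give t = 0, p = 1.
* Pipeline runs echo every defaulted parameter into a JSON RunRecord so
  any output is reproducible from the record alone.

## Problem sizes used in the validation suite

Analytic phantom checks use exact or near-exact tolerances (circle
curvature to 1e−9; noiseless tensor inversion to 1e−9 relative). The
simulation-based checks use: 50-seed plates for the outlier-flagging
operating characteristics; a 20-master-seed sweep of 10-vs-10 cohorts for
truncation power; and 1000 null comparisons for the type-I rate. These
sizes put Monte-Carlo error comfortably below the decision margins they
feed.

## Known limitations

* Tractography itself (FOD estimation, probabilistic tracking) is out of
  scope; tractograms are consumed, and the bundle generator stands in.
  Tracking parameters seen in study configs (step 100 μm, 2M streamlines)
  are recorded for provenance only.
* The published assay's Excel-based fitting tool is unavailable, so RPPM
  correctness is established by recovery from known ground truth rather
  than by output matching.
* The TWI-MC curvature estimator is one defensible realisation of
  "average track curvature"; the original study does not define its
  estimator or weighting.
* Registration, bias-field correction, template construction and
  multi-shell diffusion models are out of scope.
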