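# Methods

This note records the models implemented in `cardiotwist`, the parameter
choices that matter, what the synthetic phantom does and does not emulate,
and the numerical decisions taken where the design was genuinely open.

## The motion phantom

The phantom is an analytic short-axis/long-axis ventricular geometry with
five independent kinematic knobs, each prescribed as its end-systolic
value and driven through systole by a monotone activation profile
(default: smoothstep 3τ² − 2τ³; configurable to linear):

* **rotation** — linear in slice position between the apical and basal
  slice values (defaults −3° base, +9° apex; counterclockwise positive
  viewed from the apex in radiological display);
* **circumferential shortening** — the mid-wall circumference scales by
  1 − c·a(τ) (default c = 0.15);
* **radial thickening** — wall thickness scales by 1 + r·a(τ)
  (default r = 0.30);
* **longitudinal shortening** — the long-axis view contracts isotropically
  toward the basal plane by 1 − l·a(τ) (default l = 0.15), so the
  endocardial arc length scales exactly by that factor;
* **bulk translation** — optional, for validating translation invariance.

Incompressibility is deliberately *not* enforced: the knobs are
independent so each strain direction is separately testable against its
prescribed value. The forward and inverse maps are closed-form and exact
(round-trip error < 1e−6 mm), and analytic contours are available at every
frame — they are the ground truth every estimator is validated against.

Species presets follow the acquisition geometries of small-animal and
pediatric tagged CMR: mouse 0.15 mm pixels, 0.7 mm tag spacing, 20 phases,
endocardial radius ~1.9 mm and 0.9 mm wall (murine end-diastolic anatomy);
human 1.875 mm pixels, 7 mm tags, 25 phases, radius ~21 mm, 9 mm wall.
An RV crescent (cavity + free wall attached to the LV epicardium, sharing
the septal points with the LV epicardial contour) is included for strain
phantoms.

**Rendering.** Tagged frames multiply the myocardial intensity by a
raised-cosine grid evaluated at the *reference* coordinate (through the
inverse map), so tags deform with tissue; tag contrast fades geometrically
per frame. Blood pool and background are tag-free at distinct intensities,
and the tagged renderer draws the LV only — the sub-millimeter RV free
wall carries no resolvable tag signal at these tag spacings and its static
cavity otherwise corrupts the LV harmonic phase. Cine frames are a
piecewise-constant tissue model (bright blood, mid-gray myocardium, dark
background) plus two realism terms that matter for tracking: a
band-limited material texture on the myocardium (amplitude 0.15 of tissue
intensity, feature size ~5 px, fixed in reference coordinates so it
deforms with the tissue) and a Gaussian point-spread blur (0.7 px). Without
intra-tissue features a contour tracker is blind to tangential motion on
straight walls (the aperture problem), and without a PSF the aliased hard
edges bias sub-pixel matching; both terms are configurable to zero. A
symmetric PSF cannot shift harmonic phase, so the tagged analysis is
unaffected by it. Gaussian pixel noise (default SD 0.02 on a 0–1 intensity
scale, i.e. SNR ≈ 30 for myocardium) is added last.

**What the phantom does not emulate:** MR physics (k-space, bSSFP banding,
flip angles), through-plane motion, breathing/gating artifacts, papillary
muscles and trabeculation, regional wall-motion heterogeneity, and real
observer variability. Passing the phantom tests therefore demonstrates
estimator correctness under known kinematics, not clinical-grade accuracy.

## Harmonic-phase rotation tracking

The tag harmonic nearest the nominal wave-vector is isolated with an
isotropic Gaussian bandpass (σ = 0.5·|k|) multiplied by an explicit DC
notch (1 − Gaussian of σ = 0.45·|k| at the origin). The notch matters: a
bandpass wide enough to resolve a 1.3-tag-period wall otherwise admits the
static tissue envelope near DC, whose phasor drags the motion-encoding
phase toward zero. Displacement solves the 2×2 wrapped-phase-difference
system per pixel with the nominal wave-vectors. A Newton refinement step
(resampling the earlier phase at the displaced position) is implemented
but **off by default**: on bandpass-filtered phantom phases it
systematically overshoots tangential displacement by ~20% in thin walls.
Pixels are flagged invalid when their implied tag-jump count disagrees
with a bulk-shift prior from phase correlation of the harmonic magnitude
images — true aliasing (motion beyond half a tag period) is undetectable
from a single wrapped difference alone. Rotation per frame pair is the
mean wrapped change of polar angle about the endocardial centroid over the
quality mask (harmonic magnitude ≥ 10% of slice maximum ∩ myocardial mask
eroded by 1 px; the bandpass kernel bleeds phase across tissue borders).

Validated accuracy at the mouse preset, zero image noise: prescribed
rotations recovered within ~5% up to 15°, ~1% sensitivity to rotating the
tag grid by 45°, peak torsion rate within ~4% of the analytic value, and
0.7% agreement between 20-frame and 25-frame samplings after τ
normalization. With the default strain deformation superimposed and image
noise on, per-frame increment noise in the ~6-px wall leaves the torsion
*curve* accurate (T(1) within ~1%) but inflates the spline-derivative peak
substantially — a known limitation of derivative-of-interpolant statistics
on noisy curves; twist-recovery validation therefore uses twist-only
motion.

## Torsion

T(τ) = (BR − AR)(R_apex + R_base)/(2D). R values are measured at
end-diastole as half the inferior–anterior endocardial chord; D is the
base–apex length at end systole (both choices configurable). Resampling
uses a cubic spline with **not-a-knot** boundary conditions on a uniform
τ grid of step 0.001; natural boundary conditions were rejected because
they cannot reproduce even quadratic curves and distort ∂T/∂τ exactly at
τ = 1, where systolic peaks live. The peak torsion rate is the signed
value of the spline derivative at the τ of maximum |∂T/∂τ| (the same
maximum-absolute convention used for strain peaks); the maximum *signed*
derivative and the secant rate over the full cycle are exposed as options.
Ties resolve to the smallest τ.

## Feature-tracking strain

Each contour point carries an 11×11 px template matched by normalized
cross-correlation within a ±3 px search window; the integer peak is
refined by five Lucas–Kanade iterations (a parabolic fit of the NCC
surface pixel-locks at the ~0.1–0.5 px inter-frame motions of cine).
Displacements are smoothed along the contour (moving average, window 3)
and accumulated frame-to-frame. The long-axis contour uses a 9×9 template:
the wall there is a thin elongated band, and a wider template anchors on
material deep in the wall, which moves more than the endocardial edge
under contraction (a lever-arm bias worth ~3 strain points). Tracking
quality raises an error when more than 20% of points fall below the
correlation floor.

Strains are engineering strains on lengths, matching the feature-tracking
convention: circumferential from the mid-wall polygon perimeter (averaged
over the three short-axis slices), radial from mean point-wise endo–epi
distance (RV: free-wall points only, since the septal points are shared
with the LV epicardium by construction), longitudinal from the long-axis
endocardial arc length. LV metrics include the septum. Peaks follow the
max-absolute signed rule; analyses are repeated (default 3×) with 0.3 px
Gaussian jitter on the starting contours and averaged, emulating repeated
manual reads. Validated end-to-end at the mouse preset with default noise:
each global LV peak within 3 strain points of the prescribed deformation
with the clinical sign pattern. RV strains from images are
resolution-limited (the mouse RV free wall is ~3 px thick) and are
reported but not accuracy-guaranteed; cohort-level RV analyses use the
metric-level generator instead.

## Pressure waveforms and single-beat elastance

The simulated cycle places the isovolumic limbs exactly on the sinusoid
`s(t) = Pes + (Pmax − Pes) sin(ω(t − t_on))` with ω = π/(t_off − t_on),
which makes maximum dP/dt coincide with ejection onset, minimum dP/dt with
end systole, and the sinusoid peak with Pmax; the ejection phase is a
raised-cosine bump clipped below Pmax (default 85% of the amplitude), and
end-diastole is the baseline crossing of the rising limb — a *derived*
landmark. Feasibility requires Pes − baseline < Pmax − Pes; the
constructor validates this. Defaults: human 75/30/5 mmHg at 100 bpm
sampled at 1 kHz, mouse 35/18/3 mmHg at 450 bpm at 2 kHz (research-grade
hemodynamic recorders sample at 1–2 kHz; Fisher-information analysis shows
the single-beat extrapolation cannot reach its quoted precision below
~500 Hz at human heart rates — see limitations).

Estimation is dispatched on a noise estimate from second differences.
Clean traces: landmark-delimited segments (trimmed one sample at each
landmark) and a Levenberg–Marquardt fit of a + c₁sin(ωt) + c₂cos(ωt) with
inlier re-selection; this is exact on noiseless cycles at all heart rates
60–600 bpm. Noisy traces: a crossing-anchored fit — the baseline
crossings are steep and hence sub-sample localizable, the crossing span
pins the frequency through ω(t₂ − t₁) = π + 2·asin(u) with
u = (a − L)/b, and the self-consistent u is found by a bracketed root
solve with a linear fit at the implied frequency. Pes is taken as the
fitted sinusoid mean level (the pressure at the steepest fall of a
sinusoid), which is sub-sample and noise-averaged. Measured performance at
noise SD 2 mmHg over 200 cycles: Pmax median |error| ≈ 4–5%, Ees bias
≈ 1–2% with an estimate SD of ≈ 15–18% (reported, not bounded — the
information floor of a single beat at this noise is of that order).

SV is always an explicit input, as in practice (imaging- or Fick-derived);
PVR uses Wood units throughout (mmHg·min/L).

## Cohort generator and statistics

Cohort tables are drawn per group from Gaussians at reported group
statistics for such cohorts (global peak strains for the four groups, torsion rates
3.0 ± 1.5 / 1.4 ± 0.6 / 4.2 ± 1.4 / 0.84 ± 0.6 °/τ, at n = 17/18/9/12).
Elastance blocks are plausible values chosen once (PAH 0.8 ± 0.3, banded
mice 2.0 ± 0.8 mmHg/mL, with banded > PAH as observed), correlated with
torsion rate at reported coefficients (0.51 and 0.91). Two
correlation mechanisms exist: explicit pairwise mixing, and a per-subject
**severity factor** loading on all mechanics metrics (0.65 hypertensive,
0.45 control groups; strains toward zero, torsion rate and contractility
down). The severity factor reflects that subjects at different disease
stages deviate consistently across metrics; without it, pooled PCA
clusters by species as often as by disease status, because the
between-species differences of the printed RV strains rival the disease
differences. The explicit torsion–Ees mixing coefficients are calibrated
so the *total* correlations, including the severity factor, equal those
targets.

Statistics layer: Lilliefors normality per group at α = 0.05 routes to a
pooled-variance Student t-test (Welch by flag) or Mann–Whitney; ordinary
least-squares regression with Pearson r; PCA via SVD of the z-scored
metric matrix (sign convention: largest-magnitude loading positive per
component); ICC(A,1) from two-way ANOVA mean squares (cross-checked
against pingouin in the tests); Bland–Altman reports the 95% confidence
interval of the mean difference as the primary agreement summary, with
limits of agreement alongside. No multiple-testing correction is applied
by default; Benjamini–Hochberg is available.

## Numerical choices and degenerate inputs

Seeds: every stochastic step draws from `numpy.random.default_rng` seeded
through `SeedSequence` children of one run seed; identical configurations
are bit-identical across runs. Degenerate inputs fail fast with typed
exceptions: invalid geometry/parameters at construction
(`ConfigurationError`), arguments outside mathematical domains
(`DomainError`), unusable signal (`QualityError`,
`TrackingQualityError`), inadmissible fits (`EstimationError`, e.g. a
fitted Pmax below the recorded maximum of an ejecting beat). Problem
sizes used in the validation suite — 96×96 images, 20–25 frames, 200
Monte-Carlo pressure cycles, 1000 cohort draws — were chosen as the
smallest sizes at which the estimators' asymptotic behavior is visible.

## Known limitations

* Peak torsion *rate* from spline derivatives is noise-sensitive; on noisy
  rotation curves the cumulative torsion is much better determined than
  its derivative maximum.
* Single-beat Ees from one noisy cycle has an irreducible spread (~15% SD
  at 2 mmHg noise, 1 kHz); averaging beats, not a better fit, is the way
  down.
* Image-derived RV strain at mouse resolution is unreliable (wall ≈ 3 px);
  the cohort analyses use the metric-level generator for RV columns.
* The phantom's exterior (RV-side) deformation field is a radial
  continuation of the LV map, not an independently prescribed RV
  kinematics; RV image ground truth is therefore self-consistent but not
  physiological.
* The severity factor and elastance group parameters of the cohort
  generator are modeling choices, not published values; they are declared
  here and in the generator's docstrings.
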