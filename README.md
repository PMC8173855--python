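# cardiotwist

Biventricular myocardial mechanics from tagged and cine cardiac MR, built
for cross-species work: the same analysis chain runs on mouse-scale
(7 T, 0.15 mm pixels, 0.6–0.8 mm tags, ~400 bpm) and pediatric-scale
(1.5 T, 1.875 mm pixels, 6–8 mm tags, ~90 bpm) acquisitions. Because
clinical and animal image data of this kind are rarely shareable, the
package ships an analytic ventricular motion phantom that generates every
input the pipeline needs — SPAMM-tagged and cine image stacks with known
deformation, contours, single-beat pressure waveforms, and cohort tables —
so every estimator can be validated against exact ground truth.

## What it computes

**LV torsion and peak torsion rate.** Per-slice rotation is recovered from
SPAMM-tagged short-axis stacks by harmonic-phase (HARP) analysis: the first
spectral harmonic of the tag pattern is isolated with a Gaussian bandpass,
the per-pixel 2×2 wrapped-phase-difference system gives the displacement
field, and the mean angular component about the endocardial centroid gives
the rotation curve. Torsion combines basal (BR) and apical (AR) rotation
with geometry,

    T(τ) = (BR − AR) · (R_apex + R_base) / (2D),

with R the endocardial radii (half the inferior–anterior chord) and D the
base–apex length. Time is normalized to the fraction of systole
τ ∈ [0, 1], removing heart rate so mice and children are comparable; the
statistic of interest is the peak torsion rate ∂T/∂τ (°/τ), read from a
cubic spline resampled at Δτ = 0.001.

**Global strain by feature tracking.** Contours traced at end-diastole are
propagated frame-to-frame by normalized cross-correlation template
matching with Lucas–Kanade sub-pixel refinement. Global engineering
strains: circumferential = mid-wall perimeter change (%), radial = mean
endo-to-epi wall-thickness change (%), longitudinal = long-axis
endocardial arc-length change (%). Peaks are the signed value at the frame
of maximum absolute strain, with triplicate tracking runs averaged.

**Single-beat end-systolic elastance.** From one RV pressure cycle, the
isovolumic contraction and relaxation limbs are fit with a sinusoid whose
peak is the maximum theoretical pressure Pmax; then
Ees = (Pmax − Pes)/SV, Ea = Pes/SV, compliance = SV/PP, and
PVR = (mPAP − PCWP)/CO (Wood units), plus Laplace wall stress P·r/h.

**Cohort statistics.** Lilliefors-routed two-group tests (pooled-variance
t-test or Mann–Whitney), univariate regression, z-scored PCA with biplots,
and observer agreement (ICC(A,1) and Bland–Altman with the 95% CI of the
mean difference).

## Worked example

`examples/01_twist_and_torsion.py` builds a mouse phantom twisting −3° at
the base and +9° at the apex and recovers the torsion curve end to end:

```
recovered basal rotation at end systole : -2.90 deg (prescribed -3.00)
recovered apical rotation at end systole: +8.60 deg (prescribed +9.00)
end-systolic torsion T(1)               : -2.874 deg (analytic -3.000)
peak torsion rate dT/dtau               : -4.316 deg/tau (analytic -4.500) at tau = 0.45
```

The recovered rotations sit within ~5% of the prescribed motion and the
peak torsion rate within ~4% of the analytic value for the prescribed
curves. The other examples cover strain tracking (`02`), single-beat
elastance (`03`, Pmax 75.0 recovered exactly from a clipped waveform whose
recorded maximum is 68.2 mmHg), and the cohort statistics layer (`04`,
where the first principal component of z-scored mechanics separates
hypertensive from control subjects across species).

A thin CLI mirrors the pipeline stages
(`cardiotwist simulate|track|torsion|strain|hemo|cohort|all`), e.g.

```bash
cardiotwist simulate --preset mouse --seed 1 --outdir out/
cardiotwist torsion --preset mouse --seed 1 --outdir out/
```

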