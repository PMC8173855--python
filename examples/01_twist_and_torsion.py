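"""Recover LV torsion from a tagged-image phantom.

Builds a mouse-scale phantom twisting -3 deg at the base and +9 deg at the
apex, renders SPAMM-tagged short-axis stacks, tracks rotation by harmonic
phase, and derives the torsion curve and its peak rate in deg per tau
(tau = fraction of systole, which removes heart rate).
"""

from cardiotwist.phantom import PhantomSpec
from cardiotwist.pipeline import torsion_from_phantom

spec = PhantomSpec.mouse(
    basal_rotation_deg=-3.0,
    apical_rotation_deg=9.0,
    circ_shortening_frac=0.0,
    radial_thickening_frac=0.0,
    long_shortening_frac=0.0,
)
rate, curve, rotations = torsion_from_phantom(spec, tag_noise_sd=0.0, fade_per_frame=1.0, seed=1)

r_a, r_b = spec.endo_radius_mm["apex"], spec.endo_radius_mm["base"]
t_es = (spec.basal_rotation_deg - spec.apical_rotation_deg) * (r_a + r_b) / (2 * spec.base_apex_length_mm)
analytic_peak = t_es * 1.5  # smoothstep activation: max slope 1.5 at mid systole

print(f"recovered basal rotation at end systole : {rotations['base'].rotation_deg[-1]:+.2f} deg (prescribed -3.00)")
print(f"recovered apical rotation at end systole: {rotations['apex'].rotation_deg[-1]:+.2f} deg (prescribed +9.00)")
print(f"end-systolic torsion T(1)               : {curve.torsion_deg[-1]:+.3f} deg (analytic {t_es:+.3f})")
print(f"peak torsion rate dT/dtau               : {rate.peak_rate_deg_per_tau:+.3f} deg/tau "
      f"(analytic {analytic_peak:+.3f}) at tau = {rate.tau_at_peak:.2f}")
print()
print("The peak torsion rate is the cross-species metric: normalizing time to the")
print("systolic fraction tau makes it comparable between mice (~400 bpm) and")
print("children (~90 bpm).")
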