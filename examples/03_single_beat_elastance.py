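"""Single-beat RV end-systolic elastance from one pressure cycle.

Simulates an RV pressure waveform whose isovolumic limbs lie on a sinusoid
with a known theoretical peak (Pmax = 75 mmHg), then recovers Pmax by the
single-beat sinusoid fit and derives the coupling indices.
"""

from cardiotwist.hemo import analyze_waveform, pvr, wall_stress
from cardiotwist.phantom import PressureParams, simulate_pressure

params = PressureParams(pmax_true=75.0, pes_true=30.0, stroke_volume_true_ml=30.0)
waveform = simulate_pressure(params, seed=1)
result = analyze_waveform(waveform, sv_ml=30.0, mpap=49.0, pcwp=9.0, co_l_min=5.0)

print(f"recorded maximum pressure : {waveform.pressure.max():6.1f} mmHg (ejection is clipped)")
print(f"extrapolated Pmax         : {result.pmax_mmhg:6.1f} mmHg (truth 75.0)")
print(f"end-systolic pressure Pes : {result.pes_mmhg:6.1f} mmHg (truth 30.0)")
print(f"Ees = (Pmax - Pes)/SV     : {result.ees_mmhg_per_ml:6.2f} mmHg/mL (truth {params.ees_true:.2f})")
print(f"Ea  = Pes/SV              : {result.ea_mmhg_per_ml:6.2f} mmHg/mL")
print(f"compliance = SV/PP        : {result.compliance_ml_per_mmhg:6.2f} mL/mmHg")
print(f"PVR = (mPAP - PCWP)/CO    : {result.pvr_wood:6.2f} Wood units")
print(f"Laplace wall stress P*r/h : {wall_stress(60, 2.0, 0.5):6.1f} mmHg (P=60, r=2, h=0.5)")
print()
print("Ees is the load-independent contractility index; the theoretical peak")
print("Pmax is what the ventricle would generate against a closed valve.")
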