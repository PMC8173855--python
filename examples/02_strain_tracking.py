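"""Global myocardial strain by feature tracking on cine phantoms.

The phantom prescribes 15% circumferential shortening, 30% radial
thickening and 20% longitudinal shortening; contours traced at
end-diastole are propagated by template matching and the three global
engineering strains are read off the tracked contours (triplicate reads
averaged, as in clinical feature-tracking practice).
"""

from cardiotwist.phantom import PhantomSpec
from cardiotwist.pipeline import strain_from_phantom

spec = PhantomSpec.mouse(
    circ_shortening_frac=0.15, radial_thickening_frac=0.30, long_shortening_frac=0.20
)
peaks, curves = strain_from_phantom(spec, cine_noise_sd=0.02, repeats=3, seed=7)

print("global LV peak strains (averaged over 3 tracking repeats):")
print(f"  circumferential: {peaks.peaks['lv_circ']:+6.1f} %   (prescribed -15)")
print(f"  radial         : {peaks.peaks['lv_radial']:+6.1f} %   (prescribed +30)")
print(f"  longitudinal   : {peaks.peaks['lv_long']:+6.1f} %   (prescribed -20)")
print(f"  peak displacement: {peaks.peaks['lv_displacement']:.2f} mm")
print()
print("Signs follow the clinical convention: shortening (circumferential,")
print("longitudinal) is negative, wall thickening (radial) is positive.")
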