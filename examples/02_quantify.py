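"""Quantify one phantom with both VOI-placement methods.

The fixed method puts the sphere on the muscle's cross-section centroid at an
anatomical bone position (e.g. 50% of femur height); the hotspot method puts
it on the highest uptake voxel confirmed on consecutive slices.  With a focal
lesion away from the fixed plane, the hotspot VOI reads distinctly higher.
"""

from petmuscle import PatternSpec, SubjectParams, generate_atlas, generate_phantom
from petmuscle.pipeline import quantify_phantom

atlas = generate_atlas()
subject = SubjectParams(weight_kg=70.0, dose_mbq=350.0)
patterns = {
    ("quadriceps", "R"): PatternSpec("unifocal", 1, amplitude=2.0, radius_mm=14.0),
    ("psoas", "L"): PatternSpec("multifocal", 2, amplitude=2.0, radius_mm=6.5),
}
phantom = generate_phantom(atlas, subject, patterns, seed=3)

table, vois = quantify_phantom(phantom)
cols = ["muscle", "side", "method", "diameter_mm", "suv_max", "suv_peak"]
focal = table[table["muscle"].isin(["quadriceps", "psoas"])]
print(focal[cols].round(3).to_string(index=False))
# suv_peak (the mean over a 12 mm neighborhood around the best position) is
# the headline outcome measure: for lesioned muscles the hotspot row exceeds
# the fixed row; for homogeneous muscles the two methods agree within noise.
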