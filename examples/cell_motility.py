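"""B-lineage cell tracking and motility metrics on a synthetic movie.

Generates a time lapse in which B cells perform a persistent random
walk at 4 µm/min and plasma cells jitter in place, detects the cells in
every frame, links them into tracks, applies the >10-time-point filter,
and summarizes mean velocity and displacement rate per class.
"""

from limbquant import SceneConfig, motility, synth

cfg = SceneConfig(
    volume_extent=(150.0, 150.0, 48.0),
    fov_diameter=150.0,
    voxel_size=(1.0, 1.0, 2.0),
    n_frames=20,
    frame_interval=30.0,
    seed=7,
)
stack, truth = synth.generate_cell_scene(
    cfg, n_b=8, n_pc=4, motion=synth.MotionParams(b_speed=4.0)
)

per_frame = [motility.detect_cells(stack, frame=t) for t in range(stack.n_frames)]
tracks = motility.link_tracks(per_frame, max_step=10.0)
kept = motility.filter_tracks(tracks, min_timepoints=10, frame_interval=30.0)
table = motility.motility_table(kept, frame_interval=30.0)

print(f"cells simulated: {truth.n_b} B cells, {truth.n_pc} plasma cells")
print(f"tracks linked: {len(tracks)}, retained after the 5-min filter: {len(kept)}\n")
print(table.to_string(index=False))

by_class = table.groupby("class")["mean_velocity_um_min"].agg(["mean", "std", "count"])
print("\nmean velocity by class (µm/min):")
print(by_class.to_string())

b = table.loc[table["class"] == "B cell", "mean_velocity_um_min"]
pc = table.loc[table["class"] == "plasma cell", "mean_velocity_um_min"]
if len(b) >= 2 and len(pc) >= 2:
    cmp_ = motility.compare_groups(b, pc, metric="mean_velocity")
    print(f"\nWelch t-test B vs plasma: p={cmp_.p_value:.3g} {cmp_.stars}")
print(
    "\nB cells move at roughly the configured walk speed while plasma cells\n"
    "stay confined; every track's displacement rate is bounded by its mean\n"
    "velocity."
)
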