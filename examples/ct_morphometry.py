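"""µCT morphometry: cortical thickness and BV/BS on phantoms.

A line crossing the two cortices of a long-bone shaft sees two
intensity peaks; fitting a sum of two Gaussians reports each wall's
thickness as the fitted FWHM. Bone volume / bone surface comes from
voxel and exposed-face counting on a binarized stack.
"""

from limbquant import morphometry, synth

grid, truth = synth.generate_ct_phantom(
    wall_thicknesses=(200.0, 250.0), wall_separation=1500.0, voxel=10.5, noise_sd=20.0
)
mid = grid.shape[1] * truth.voxel / 2.0
fit = morphometry.profile_thickness(
    grid, truth.voxel, (0.0, mid, mid), (grid.shape[2] * truth.voxel, mid, mid)
)
w1, w2 = fit.thickness_fwhm
print(f"fitted wall thickness: {w1:.1f} µm and {w2:.1f} µm (truth: 200 and 250 µm)")
print(f"fitted sigmas: {fit.sigmas[0]:.1f} / {fit.sigmas[1]:.1f} µm\n")

cube = synth.digital_cube(10)
result = morphometry.bone_morphometry(cube, 10.5, 0.5)
print(
    f"digital 10³-voxel cube at 10.5 µm: BV = {result.bv_mm3:.5f} mm³, "
    f"BS = {result.bs_mm2:.5f} mm², BV/BS = {result.bv_bs_mm * 1000:.2f} µm"
)
print("(exact oracle: 1000 voxel volumes and 600 voxel faces)\n")

limb = [0.92, 1.05, 0.98, 1.10]
contra = [0.95, 1.02, 1.00, 1.08]
cmp_ = morphometry.paired_compare(limb, contra)
print(
    f"paired t-test implanted vs contralateral BV (demo numbers): "
    f"t={cmp_.t_statistic:.2f}, p={cmp_.p_value:.2f} — no detectable difference."
)
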