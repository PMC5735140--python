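# Methods

This note documents the models, parameter choices, numerical details
and known limitations of `limbquant`. It covers the synthetic-data
generators first (they define what the validation suite can and cannot
show) and then each analysis stage.

## Coordinate and sampling conventions

Physical coordinates are micrometres with the origin at the stack
corner and z along the optical axis. Arrays are indexed `(z, y, x)`
(or `(t, z, y, x)`); voxel sizes and point coordinates are written
`(x, y, z)`. A voxel with index `(k, j, i)` has its centre at
`((i+0.5)vx, (j+0.5)vy, (k+0.5)vz)`, and a voxel belongs to a shape if
its centre is inside (half-open convention). The default raster mirrors
the acquisition geometry of the single-GRIN-lens microendoscope:
circular 280 µm field of view, 280 × 280 × 70 µm³ volume, 0.7 × 0.7 ×
6 µm voxels (a 350 µm scan digitized on ~507 pixels; 6 µm z-step),
frames every 30 s, point spread function of 0.8 µm FWHM laterally and
5.2 µm axially.

## Image formation model

All two-photon generators share one forward model: binary (or scaled)
label field → amplitude scaling → separable anisotropic Gaussian PSF
blur → circular field-of-view mask → Poisson shot noise on the expected
counts → additive zero-mean Gaussian read noise. The defaults are a
background of 10 counts and read noise of 2 counts, so the background
standard deviation is √(10 + 4) ≈ 3.74 counts; the signal amplitude is
chosen as `A = snr_target · √(b + r²) − b` so the foreground mean hits
the configured SNR target. The default `snr_target` of 10 leaves a
factor-two margin over the SNR ≥ 5 quality gate, reflecting that
usable sessions comfortably clear the gate rather than sitting on it.
The model deliberately omits depth-dependent aberrations, scattering,
and detector nonlinearity.

## Vessel scenes and the remodeling ground truth

Vessels are tubes of constant diameter around gently curving
centrelines. Rendering uses capsules per polyline segment (spherical
joints keep bends water-tight) with the two tube ends carved flat, so a
straight tube of length L encloses exactly π(d/2)²L up to voxelization
— the property the volume oracles rely on.

Remodeling is realized by sliding each vessel's arc-length window along
a fixed mother curve: between sessions a vessel with class rate r
(fraction of volume per 24 h) retracts r/2 of its length at one end and
grows r/2 of new length at the other. The symmetric-difference volume
is then r times the later-session volume by construction, independent
of vessel length, and the recorded ground truth is recomputed exactly
from the rendered per-vessel masks. Default class rates are 0.4 / 0.15
/ 0.05 per 24 h for small / mid / large vessels — free parameters of
the generator, chosen to produce a clearly diameter-dependent regime.

Two placement constraints keep the scene analysable: distinct vessels
are rejection-sampled to keep ≥ 8 µm of clearance (tubes that touch, or
nearly touch and are bridged by PSF blur, merge into one connected
component and can no longer be classified per vessel), and curves are
self-avoiding (wall reflections would otherwise fold a tube back onto
itself and corrupt the flat end carve). When a crowded scene leaves no
room, the vessel is retried at 0.75×, 0.55× and 0.4× of its nominal
length — legitimate because the remodeling fraction is
length-independent.

Diameters are drawn from 9–14, 19–31 and 39–49 µm, i.e. at least about
one axial voxel inside the class bins [5, 15), [15, 35), [35, ∞). The
local-thickness estimator quantizes at the voxel scale (see below), and
a validation phantom should not place objects on a decision edge; the
generator therefore probes the class *contrast*, while the classifier
boundary itself is tested analytically.

What the vessel scenes do **not** emulate: branching topology, flow or
perfusion, lumen inhomogeneity, vessel wall signal, granulation-tissue
texture, or session-to-session deformation beyond rigid identity.
Passing the recovery tests therefore shows the statistic and its
stratification work on well-formed vasculature, not that segmentation
is robust to every real-tissue artifact.

## Cell scenes

B cells perform a persistent random walk with fixed per-frame step
length `speed · Δt` (default 4 µm/min, persistence 0.7); plasma cells
take Ornstein–Uhlenbeck-like jitter steps (s.d. 0.3 µm) confined within
2 µm of an anchor, reflecting their sessile residence in marrow niches.
Volumes are drawn uniformly from 150–450 µm³ (B cells) and
600–1500 µm³ (plasma cells), respecting the 500 µm³ class boundary by
construction. Cells are rendered as homogeneous spheres, placed without
contact inside the square inscribed in the circular field of view (a
cell outside the FOV renders to nothing and would be untestable ground
truth). Not emulated: cell shape and polarization, intensity
heterogeneity, division, contact interactions, entry/exit through the
FOV boundary.

## Photoactivation scenes

Frame 0 is the pre-activation baseline; post-activation sessions
(default 0, 12, 24, 36 h) set the ROI (default 75 × 75 × 30 µm³,
centred) to `baseline · fold · exp(−(k_turnover + k_emigration)·t)`
with fold = 100. Turnover and emigration are collapsed into a single
exponential rate; the analysis side offers a two-component fit for
series where the pools separate, but experiments at these session
counts constrain only the combined decay. The default turnover of ln 2 / 24 h⁻¹
keeps signal above threshold through 36 h, matching the persistence
regime the stability analysis is designed to detect.

## CT phantoms

Two parallel cortical walls perpendicular to x, each wall a Gaussian
intensity profile whose FWHM is the wall thickness (defaults 200 and
250 µm, 1500 µm apart, 10.5 µm isotropic voxels, optional additive
Gaussian noise). A digital solid cube provides the exact face-counting
oracle for BV/BS.

## Analysis stages — numerical choices

**Segmentation** (`vessels.segment_vessels`): Gaussian smoothing
(default 2 µm FWHM, anisotropy-aware), Otsu threshold unless a fixed
value is given, removal of 26-connected components below 500 µm³,
filling of enclosed holes. An all-background result returns an empty
mask with a warning, not an error.

**Local diameter** (`vessels.local_diameter`): per-voxel diameter is
2 × EDT evaluated on the medial skeleton and propagated to every
foreground voxel from its nearest skeleton point. Because
`skeletonize` assumes isotropic spacing, anisotropic masks are
resampled (nearest-neighbour) to an isotropic grid at the smallest
voxel edge first. The +v₀ term corrects the centre-to-centre EDT to
the physical surface (the boundary lies ~half a voxel beyond the last
foreground centre on each side); residual bias is about −1 axial voxel
for tubes a few voxels across. Components one voxel thick along an
axis are clamped to the voxel size with a warning.

**Remodeling statistic** (`vessels.remodeling_statistic`): vessel
instances are 26-connected components of the union of the two sessions'
masks (the only definition that keeps a partially remodeled vessel in
one piece); class membership uses the median local diameter over the
later session's voxels, with half-open bins and ties going to the lower
class; components with median diameter below the smallest edge are
excluded; components absent at the later session have an undefined
statistic and are tallied as fully disappeared rather than averaged.
The headline `delta_norm` is the unsigned symmetric difference over
`V_t24`; a signed variant `(V_appear − V_disappear)/V_t24` is exposed
as `delta_signed` for net growth/regression questions.

**Registration** (`vessels.pair_sessions`): optional integer-voxel
translation by FFT cross-correlation of the binary masks, restricted to
±10 voxels per axis; rolled-in voxels are invalidated. Off by default —
the implant itself fixes the frame, which the photoactivation stability
analysis verifies independently.

**Cell detection** (`motility.detect_cells`): smoothing, global
threshold, 26-connected components, and a watershed split of touching
cells seeded at distance-transform maxima (peak separation default
4 µm). Volumes below 50 µm³ are discarded as debris.

**Track linking** (`motility.link_tracks`): greedy nearest-first
assignment frame to frame under a 10 µm/frame step limit (≈ 20 µm/min
at 30 s — comfortably above B-cell speeds), gap bridging up to 2 frames
with the step limit scaled by the gap, deterministic tie-break by
(distance, track id, detection order) after sorting detections by
position, which makes the result independent of input order. At the
cell densities of these scenes greedy assignment agrees with the
exhaustive minimum-total-distance assignment (verified against a
brute-force oracle in the tests); a full optimal assignment was not
needed.

**Track filter**: strictly more than 10 time points (so an 11-point
track at 30 s — 5 min — is the shortest retained). Idempotent.

**PSF fitting** (`optics.fit_bead`): axially symmetric 3D Gaussian plus
constant background, least squares within a (±2.5 µm lateral,
±13 µm axial) window; rejection gates: residual RMS > 20 % of
amplitude, fitted centre > 1 voxel from the seed, or width pinned at
the window bound. The axial FWHM comes from the full 3D fit rather
than a 1D axial profile; on noiseless model data the two coincide, and
the choice is flagged for sensitivity testing on real aberrated stacks.
Bead detection guards the configured intensity percentile with a robust
median + 6·MAD floor so sparse-bead stacks do not flood the suppressor
with noise maxima.

**SNR** (`optics.compute_snr`): foreground mean over background
standard deviation. If no background mask is supplied, background
voxels are those outside the foreground mask below its 20th intensity
percentile — a conservative signal-free floor. This truncation makes
the default-procedure SNR an upper-tilted estimate (the constructed
mask variant is exact); the quality gate is one-sided, so the bias is
acceptable and documented.

**Decay fitting** (`photoact.fit_decay`): single exponential above a
fitted baseline via least squares, rate initialised from the endpoint
log-ratio; non-decreasing series yield rate ≤ 0 with a warning rather
than an error. Exact recovery on noiseless model data is a test
invariant.

**CT profile fit** (`morphometry.profile_thickness`): trilinear
interpolation of 400 samples along the line, initial peak guesses from
the two dominant well-separated smoothed maxima, then a 7-parameter
two-Gaussian + baseline least squares. "Walls unresolved" is raised
when fewer than two distinct peaks exist or the fitted centres are
closer than half the summed FWHMs. Thickness is reported both as σ and
as FWHM; FWHM is the headline because it is the conventional
full-width thickness surrogate. Contralateral stacks are mirrored by an
axis flip so line placements transfer.

**Bone morphometry**: BV from voxel counting, BS from exposed-face
counting (faces against background or the grid boundary). Face
counting slightly overestimates curved surfaces relative to a mesh
but is exact on digital phantoms and cancels in ratio comparisons at
~10 µm voxels.

**Statistics**: one-way ANOVA across diameter classes (classes with
fewer than two usable records are dropped with a warning), Welch
two-sample t-tests for group comparisons with significance stars at
0.05/0.01/0.001, paired t-tests for implanted-vs-contralateral
morphometry, Bonferroni correction for pairwise follow-ups. Type-I
error calibration of these wrappers is exercised at 1000 null
simulations in the test suite.

## Determinism and problem sizes

One master seed fans out to per-stage seeds via a `SeedSequence` mixed
with a CRC32 stage tag, so any stage reruns reproducibly in isolation
and identical configuration + seed gives bit-identical stacks, tables
and statistics.

The validation suite runs the vessel-recovery study at 220 × 220 ×
72 µm³ with 1 × 1 × 3 µm voxels and six vessels per scene (3 small, 2
mid, 1 large) over 20 seeds — a sampling chosen so a full recovery
study completes in about a minute while keeping ≥ 3 voxels across the
smallest vessel diameter. PSF Monte-Carlo uses 100 single-bead stacks
at calibration sampling (0.3 × 0.3 × 0.6 µm). Default-geometry scenes
(280 µm FOV) are exercised for generator calibration and the SNR gate.

## Known limitations

- Real in-vivo motility means, remodeling magnitudes and BV/BS values
  exist only as figures in the source experiments, so recovery is
  validated against synthetic ground truth, not published numbers.
- The local-thickness estimator carries a ≈ −1 voxel quantization bias;
  diameters within one voxel of a class edge can be misclassified.
- The greedy tracker has no merge/split handling and will swap
  identities if cells pass within the step limit of each other.
- The single-exponential decay model conflates turnover and emigration;
  the two-component fit is identifiable only with many well-spaced
  sessions.
- Segmentation inflates `delta_norm` for the smallest vessels under
  noise (boundary voxels flip between sessions); orderings are robust
  to this, absolute small-class magnitudes less so.
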