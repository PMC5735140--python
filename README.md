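# limbquant

Quantification pipeline for longitudinal microendoscopic imaging of the
femoral bone marrow. A gradient-index (GRIN) lens implant fixed to the
mouse femur allows two-photon imaging of the same deep-marrow volume
across days to months; `limbquant` implements the image analyses such an
experiment needs — and a seeded synthetic-data generator that emulates
the acquisition, so every stage is testable end to end without any
acquired data.

## What it computes

**Vessel remodeling, stratified by diameter.** Two registered sessions
of a tracer-labelled vessel channel are segmented and split into
appearance (present only at the later session) and disappearance
(present only at the earlier one). Per vessel component the normalized
volume change is

```
delta_norm = (V_appear + V_disappear) / V_t24
```

where `V_t24` is the vessel's volume at the later session. Components
are classified by median local diameter (local-thickness transform:
twice the Euclidean distance-to-background on the medial skeleton,
propagated over the cross-section) into small [5, 15), mid [15, 35) and
large [35, ∞) µm classes, and class means are compared by one-way ANOVA
with Bonferroni-corrected pairwise follow-ups.

**B-lineage cell motility.** Cells are detected per frame
(threshold + watershed split), classified by volume — at most 500 µm³
(a 10 µm diameter sphere is ~500 µm³) is a B cell, larger is a plasma
cell — linked frame-to-frame by deterministic greedy nearest-first
assignment, and filtered to tracks present for more than 10 time points
(5 min at the 30 s frame interval). Per track: mean velocity (average
per-step speed) and displacement rate (straight-line start-to-end
distance over duration); the displacement rate never exceeds the mean
velocity.

**Optical QC.** The point spread function is estimated from
sub-resolution bead stacks by fitting an axially symmetric 3D Gaussian
per bead (FWHM = 2√(2 ln 2) σ); the signal-to-noise ratio is foreground
mean over background standard deviation, with SNR ≥ 5 as the quality
gate.

**Photoactivation stability.** A photoactivatable label switched in a
fixed ROI (default 75 × 75 × 30 µm³) brightens ~100-fold; repeated
sessions quantify ROI mean, fluorescent volume and centroid, fit an
exponential decay (turnover + cell emigration), and report centroid
drift and the persistence horizon of detectable signal.

**µCT morphometry.** Cortical thickness from a two-Gaussian fit to the
intensity profile along a line crossing both cortices (thickness =
fitted FWHM); bone volume and bone surface by voxel and exposed-face
counting; paired t-tests between implanted and contralateral femurs.

**Welfare analytics.** Total clinical score (sum of eight 0–3 factors,
range 0–24) and cage activity normalized per animal to its mean over
the three days before surgery.

## Worked example

```bash
python examples/vessel_remodeling.py
```

generates a two-session synthetic scene whose vessels turn over 40 %
(small), 15 % (mid) and 5 % (large) of their volume per 24 h, runs the
full segmentation → diameter → remodeling pipeline, and prints:

```
per-class summary (delta_norm):
class  n  delta_norm_mean  delta_norm_sd
small  3         0.427391       0.010932
  mid  2         0.158352       0.007387
large  1         0.061647            NaN

ANOVA across classes: F=887.60, p=8.31e-05
```

The estimated class means recover the generator's rates and reproduce
the ordering — small vessels remodel fastest. The other scripts in
`examples/` demonstrate cell motility, PSF/SNR QC, photoactivation
stability, µCT morphometry and the welfare analytics in the same style.

A thin CLI wraps the same functions:

```bash
limbquant simulate vessels --seed 1 --out scene/
limbquant remodel --t0 scene/vessels.tiff --t1 scene/vessels.tiff --classes 5,15,35 --out records.csv
limbquant run --seed 1 --out demo_run/       # simulate -> segment -> remodel -> compare
```

Every stack is a multi-page TIFF with a JSON sidecar carrying the voxel
size (mandatory — the package refuses stacks without physical units),
and identical configuration + seed reproduces every number bit for bit.

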