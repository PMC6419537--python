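# Methods

This note documents the models and numerical choices behind `ciliaflow`:
what the synthetic generator simulates, how the quantification operations
are defined, which defaults were chosen where the design was open, and what
the tests do and do not demonstrate about real microscopy data.

## Compartmental trafficking model

A single cell's reporter is partitioned into five well-mixed pools —
ER (releasable), apical plasma membrane, basolateral plasma membrane,
cilium, and an internalized endo-lysosomal pool — expressed as fractions of
the total so mass is conserved exactly (no synthesis or degradation on the
2 h timescale).  The dynamics are first-order:

```
ER   --k_release-->  apical (1-phi_bl)  +  basolateral (phi_bl)
basolateral  --k_transcytosis-->  apical
apical  --k_ciliary * max(0, 1 - CIL/capacity)-->  cilium
apical  --k_internalization-->  internalized   (terminal)
```

The ciliary import flux is throttled linearly by the remaining ciliary
capacity, which produces a smooth, monotone saturation of the ciliary pool
at `cilium_capacity`.  Integration is fixed-step classical RK4 at
`dt = 0.001 h`; mass is conserved to well below 1e-9 over the full window.

**Why the internalization branch exists.**  The measured apical surface
signal is the sum of the apical-membrane and ciliary pools (a side-specific
surface stain reaches the ciliary membrane, which is topologically part of
the apical surface).  Without an outflow from that union it is monotone
non-decreasing and cannot peak mid-course, yet the apical arrival series of
a synchronized wave peaks and then declines as surface reporter is
endocytosed.  A first-order apical internalization into a terminal pool is
the smallest extension that reproduces that peak while keeping mass
conservation; internalized reporter is rendered as intracellular signal.

**Defaults** (`KineticParams`): `k_release = 2.0/h`, `phi_bl = 0.62`,
`k_transcytosis = 0.5/h`, `k_ciliary = 0.45/h`,
`k_internalization = 0.7/h`, `cilium_capacity = 0.05`,
`leak_fraction = 0`.  The rate constants are not measurements; they are
calibrated once so that, on a half-hour grid over 0–2 h, the basolateral
pool peaks at 1 h, the apical surface signal peaks at 1.5 h, the ciliary
pool saturates at ~5% of total reporter by 1–1.5 h, and a 10-min-resolution
live trace first exceeds 10% of its plateau at 20–30 min and reaches 90% by
~70 min.  These landmarks, not the rates, are the model's contract.  The
sorting split `phi_bl = 0.62` makes basolateral delivery roughly (not
exactly) two-fold apical; simulations that need an exact 2:1 delivery use
`phi_bl = 2/3` with transcytosis and internalization off, in which case
BL/AP = 2 analytically at all times after release.

The ciliary import draws from the apical pool as a whole; whether real
import samples the entire apical membrane or a periciliary subregion is not
modeled (the pool is well-mixed by construction).

## Cell geometry and voxelization

The cell is a vertical cylinder: footprint diameter 10 µm, height 8 µm,
0.3 µm membrane shells (apical cap; lateral wall + basal floor =
basolateral), one cilium (length 3 µm, radius 0.12 µm, 10° tilt) on the
apical face, and a ring of non-expressing neighbor cells for background
estimation.  The cilium-to-cell volume ratio of the defaults is ~1/4600,
inside the 1/6800–1/2700 range expected for this cell type.

Voxel convention: indices are 0-based, ordered z-slowest `(z, y, x)`;
the physical coordinate of voxel `i` at spacing `d` is its center
`(i + 0.5) d` µm.  Because the cilium is thinner than a voxel, it is
rasterized by 4×4×4 supersampled fractional occupancy; intensity is
distributed by occupancy, keeping the rendered ciliary volume within a few
percent of the analytic cylinder.  The label map marks voxels with
occupancy ≥ 0.5 as cilium (a conservative "core"); `cilium_support`
(occupancy > 0) is the full footprint and is the right reference for
overlap scores against PSF-blurred segmentations.  The basal face sits
2 µm above the stack floor and the lateral/top margins are ≥ 1 µm beyond
any structure, so the unit-sum PSF loses a negligible (< 1e-6) fraction of
signal to the stack boundary.

## Image formation

Per channel, expected photons are a linear combination of per-compartment
unit maps: GFP = all pools; apical stain = apical membrane + cilium;
basolateral stain = basolateral membrane; ciliary marker = cilium only
(reporter-independent).  The PSF is an anisotropic Gaussian (lateral
σ 0.12 µm, axial σ 0.35 µm — a standard confocal approximation), applied
with a unit-sum kernel before noise so integrated intensity is conserved.
Noise is Poisson on signal + background (default 100 counts), plus
Gaussian read noise (σ 3), then clipping and integer quantization (16-bit
default).  A seed fixes all randomness; identical seeds give bit-identical
stacks.  Because image formation is linear, the PSF-blurred compartment
maps are computed once per geometry (`BlurBasis`) and reused across a
population — rendering is then noise sampling plus linear algebra.

Default sampling is (0.3, 0.1, 0.1) µm (z, y, x).  Population-scale
studies and most tests use coarser lateral sampling (0.2 or 0.25 µm),
which changes per-cell noise slightly but none of the population-level
conclusions; single-cell accuracy checks run at the default sampling.

Default intensity scales (16-bit camera counts): `photons_per_unit = 2e7`
integrated GFP photons per expression unit (≈ 10² counts/voxel above
background in the cytoplasm), `marker_photons = 2e5`, equal surface-stain
gain (`stain_gain = 1`) so a surface-to-total ratio reads out the surface
fraction directly.

## Per-cell variability

Expression level is log-normal (median 1, shape 0.4), reflecting transient
transfection; the sorting fraction `phi_bl` is normal around the population
value (sd 0.08, truncated to [0.05, 0.95]).  Mass conservation then makes
the anti-correlation structural: a cell sorting more basolaterally has
less reporter in the apical + ciliary branch.  This is the ground truth
behind the positive apical / negative basolateral slope structure; the
pipeline must merely not destroy it.

## Quantification

- **Background**: per-channel scalar, the mean over regions covering
  non-expressing cells, subtracted with clipping at zero (recorded in the
  provenance).  For the *intensity sums* of the ratios the unclipped
  subtracted values are used: over the many near-empty voxels of a cell
  region, clipping would add a positive pedestal of ~0.4σ per voxel and
  bias every ratio upward by 10–20%, whereas signed residuals cancel in
  expectation.  The MCC's "reporter-positive" support, by contrast, is
  defined on the clipped image (voxels > 0, optionally above an extra
  threshold exposed as `gfp_threshold`), which makes the "above
  background" notion explicit and testable.
- **Cilium segmentation**: Otsu's threshold computed on the positive
  voxels of the marker channel (overridable by an absolute value), 3D
  26-connected components, candidates must protrude above the apical
  reference plane (ties broken by protrusion, then brightness).  The
  apical plane is taken from ground truth/settings when available, else
  estimated as the 95th percentile of the cell-mask z distribution
  (robust to a few bright subapical vesicles).
- **Mask dilation**: the segmented marker core is dilated isotropically by
  0.25 µm (≈ 2 lateral PSF sigmas) before summing reporter signal.  The
  cilium is thinner than the PSF, so a core-only mask misses blurred
  ciliary reporter and underestimates the MCC; the dilation recaptures it
  while adding little apical-membrane contamination because most of the
  cilium lies > 1 µm above the apical plane.  With it, the recovered MCC
  on 5%-ciliary-fraction renders is 0.048 ± 0.001 (bias ≈ −4%).
- **QC**: pass iff the mask is non-empty, the principal-axis tilt from z
  is ≤ 60°, and the mask extends ≥ 1 µm above the apical plane.  These
  defaults operationalize "clearly protruding, not sharply tilted";
  excluded cells keep surface ratios but carry no MCC.
- **Cell region**: the cell mask (from ground truth, or supplied manually
  as a region mask — no automatic cell segmentation is attempted, matching
  the manual selection of isolated cells in practice) is dilated by 1 µm
  before summing, so blurred membrane signal at the cell outline is not
  clipped away; without the margin the basolateral/apical ratio acquires a
  side-dependent bias because the two stains sit at different distances
  from the mask boundary.

## Population statistics

Time courses: per-replicate per-time cell means → each replicate divided
by its own series maximum → cross-replicate mean with SEM over replicates
(n = replicates, not cells).  The per-replicate normalization makes the
result invariant to acquisition-gain differences between experiments.
QC-failed cells enter surface time courses but never MCC statistics.
Slope analysis: unweighted OLS of per-cell MCC against surface ratio
(per replicate, per side), then a two-tailed paired t-test on the
replicate-paired apical-minus-basolateral slope differences.  A
robust-fit alternative is deliberately not provided as a default; the
estimator is the plain OLS slope.

## Live trace

Frames (single-plane or 3D) are background-subtracted against a static
empty region; the marker channel is thresholded per frame (cilia drift),
the reporter summed inside the mask.  No photobleaching correction is
applied by default (an exponential correction is available), and an
optional union-with-previous-mask smoothing is off by default.  Frames
with an empty marker mask are flagged and carry NaN rather than being
dropped.

## Problem sizes

Tests and the acceptance script run at these sizes, chosen to exercise
each claim at meaningful statistics: 10 seeded renders at default
resolution for single-cell MCC recovery; 20-cell populations for the
sorting-split ratio; 50-cell × 3-replicate populations (10 independent
repetitions) for the slope-sign/significance pattern; 50-cell populations
over the five-point time grid for the peak-order check.

## What the synthetic data do and do not show

The generator reproduces the features the quantification depends on:
compartment-proportional multi-channel intensities, PSF blur comparable to
the cilium diameter, realistic shot/read noise and background, per-cell
expression and sorting variability, and non-expressing neighbors.  It does
not emulate: lateral heterogeneity within membranes (pools are well-mixed),
cell-shape variability or curved/irregular cilia, spectral bleed-through,
depth-dependent aberrations, stain accessibility differences between the
apical and basolateral chamber, or drift.  Passing tests therefore
demonstrate correctness of the estimators under the stated imaging model —
not robustness to every pathology of real acquisitions.  The QC rules and
manual cell masks are the intended guards for real data.

## Known limitations

- The kinetic model is phenomenological; rate constants are calibrated to
  qualitative landmarks, and only those landmarks should be interpreted.
- The MCC depends on the marker threshold; Otsu is a reasonable default on
  background-subtracted marker channels but bright intracellular
  acetylated-tubulin signal can require an absolute threshold override.
- Surface-ratio comparisons across sides assume equal stain gain; in real
  experiments apical and basolateral antibody accessibility may differ, so
  cross-side ratios should be interpreted within normalized series.
- No deconvolution, no Pearson/Costes co-localization variants, no
  automatic epithelial segmentation, and no drift registration for live
  imaging.
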