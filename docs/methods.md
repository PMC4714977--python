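# Methods

## Scope and model

The package quantifies how a fluorescent reporter distributes along the
long axis of rod-shaped bacteria, and between the two unequal compartments
created by polar (asymmetric) division. All image math reduces to one
parameterization: each segmented cell carries a straight centerline, an
axial coordinate s ∈ [0, 1] measured from one pole, and the set of its
pixels projected onto that axis. Cells are treated as straight rods with
hemispherical caps; bent or branched cells are out of scope (the
principal-axis centerline would foreshorten them, and the synthetic
generator never produces them).

## Synthetic micrographs

The generator exists so that every stage of the pipeline can be scored
against known ground truth. A scene holds three channels rendered from the
same geometry:

- *phase-like*: uniform unit density over the cell body. Real phase
  contrast has halos and shading this does not emulate.
- *membrane stain*: a 2-px shell along the cell outline plus a 2-px
  full-width transverse band at each septum, rendered at twice the shell
  density because a septum carries two apposed membranes.
- *reporter*: one of five localization classes — uniform cytoplasmic,
  uniform membrane, divisome ring (transverse band at a stated axial
  position), polar cap (shell within 1.5 half-widths of one pole), or
  compartment-restricted (membrane shell weighted per compartment). The
  last class models both a compartmentalized transmembrane protein and, as
  far as the classifier is concerned, a compartment-specific
  transcriptional reporter, since classification consumes only binned
  axial sums.

Optics and camera: Gaussian PSF (default σ = 0.08 µm), constant per-channel
background (0.2 density units), then optionally
counts = Poisson(photon_scale × ideal) + N(0, read_noise²), clipped at
zero. `photon_scale = None` returns the noise-free field. The pixel size
defaults to 0.065 µm/px (a typical 100× objective with a standard sCMOS
camera). Identical inputs and seed give bit-identical scenes; all noise
flows through one seeded generator consumed in fixed channel order.

Populations draw truncated-normal lengths (3.2 ± 0.6 µm on [2, 5]) and
widths (0.9 ± 0.05 µm on [0.8, 1]), random orientations, and polar septa
uniform on s ∈ [0.15, 0.30] with the pole chosen at random — the
placement regime of sporulation septa. A configurable fraction of divided
cells is "mis-compartmentalized": reporter density equal in both
compartments instead of forespore-restricted (properly compartmentalized
cells keep a 5% residual mother density, representing incomplete
confinement). Cells sit on a non-overlapping grid; crowded or touching
layouts are not emulated, so segmentation here is easier than on dense
real fields — passing tests demonstrate correctness of the measurement
chain, not segmentation robustness on crowded micrographs.

## Segmentation and meshing

Foreground is smoothed phase minus w × smoothed membrane, thresholded at a
fraction (default 0.3) of the robust signal range; components are 4-connected
and area-filtered. The weight w controls septum behaviour:

- w = 0 (sporulation mode, the pipeline default): a divided sporangium
  stays one object, as it must for a profile that spans the polar septum;
- w calibrated (chain mode): w is set so the septal score is driven to
  zero across the whole septal band on a noiseless one-cell calibration
  scene with a medial septum (pixelwise max of phase/membrane over the
  band, +5% margin). Chained cells then split at their shared septum, the
  behaviour the minicell analysis needs.

A featureless image (robust range within 6 MAD of zero) yields an empty
mask rather than an error.

Meshing takes the principal axis of the pixel cloud (exact for straight
rods). Cell length and pole position come from the 0.5-level contour of
the Gaussian-smoothed binary mask: the smoothed contour varies smoothly
with orientation, where the raw binary boundary's staircase corners made
length estimates orientation-dependent by ~2.5%. Half-widths come from
perpendicular pixel extents in axial windows. Cells touching the image
border are flagged and excluded by default, since truncated profiles would
bias population averages.

## Axial profiles

Each cell pixel is assigned to the half-open bin of its projected axial
fraction. Per-channel background — estimated as the sigma-clipped mean of
non-cell pixels — is subtracted per pixel *without* per-pixel flooring;
the per-bin sums are floored at zero instead. (Per-pixel flooring
rectifies noise and systematically inflates dim compartments, which at low
photon budgets destroys the density-ratio classifier. A sigma-clipped mean
rather than a histogram mode for the background for the same reason:
low-flux Poisson images are discrete and their mode collapses to zero.)

The per-bin ratio reporter/membrane is normalized to unit mean over valid
bins, making profiles invariant to per-channel gain and comparable across
cells. A profile with more than 25% membrane-empty bins is flagged
unusable.

Bin count: nominal 50, but capped at ~1 bin per pixel of cell length
(empty bins alias the profile) and forced odd. The odd count is a
chirality requirement: a symmetric rod always projects one pixel exactly
onto its center, which for an even bin count lies on a bin edge, and a
half-open edge assignment cannot be mirror-symmetric — left-right flipping
the image would move that pixel across the edge. With an odd count the
symmetry center falls mid-bin and oriented population profiles are
mirror-invariant to float precision.

Septa are prominent maxima of the per-bin membrane profile (lightly
smoothed, empty bins interpolated) within the interior s ∈ [0.1, 0.9];
the pole caps are membrane-bright and would otherwise be called septa.
The prominence floor is 1.5 × the median interior density: true septa sit
at ≥ 3× while shot-noise peaks at per-bin SNR ≈ 5 reach ~1.2×. A septum
with min(s, 1−s) ≤ 0.3 is polar. Divided cells are oriented by flipping
so the anchoring septum lies at s ≤ 0.5 (forespore pole at the origin);
cells whose single septum falls just past the polar cut are oriented the
same way, which keeps the density ratio meaningful when detection jitter
straddles the 0.3 boundary. With two or more septa the most polar one
anchors the orientation, prominence ties breaking toward the pole.
Undivided cells stay unoriented unless a pole is supplied — the
random-pole control samples (cell, pole) pairs without replacement with a
seeded generator.

Population profiles average each cell's unit-mean ratio, linearly
interpolated onto an absolute-µm grid from the aligned pole (default
0–3 µm at 0.065 µm spacing), out to each cell's own length; grid points
supported by fewer than `min_n` cells are masked. Averaging on absolute
distance (not normalized length) preserves the spatial scale of polar
features across cells of different lengths.

## Compartment statistics

For a divided, oriented cell: f_fs is the share of background-subtracted
reporter in bins below the septum; ρ is the ratio of per-unit-length
densities, forespore over mother. Classification uses fixed thresholds —
ρ ≥ 2 forespore-specific, ρ ≤ 0.5 mother-cell, otherwise both; total
signal below `activity_min` (settable from an inactive control
population's 99th percentile) is inactive. These thresholds replace
by-eye scoring with an explicit, automatable criterion; the 2× band is
wide enough that planted "equal density" cells (ρ ≈ 1) and
forespore-restricted cells (ρ ≈ 20 at 5% residual mother density) are
separated with ≥ 95% per-cell accuracy down to per-bin SNR 5.

The enrichment rule flags cells with mean reporter intensity strictly
above µ + 2σ, with µ and σ computed over the full population in one pass
(population SD, divisor n, no outlier trimming, flagged cells included in
µ and σ). With rare ~10× bright minicells this recovers the planted set
with precision and recall ≈ 1; the rule's single-pass character means it
would degrade if bright cells were common enough to inflate σ — it is a
rare-outlier detector, and is reported as such.

## Kinetics

Both fits are unweighted least squares on the linear scale
(`scipy.optimize.curve_fit`), matching how such data are usually fit when
no error model is published. The decay fit starts from a log-linear
regression; a fitted rate k ≤ 10⁻⁹ min⁻¹ is reported as "stable" with no
finite half-life. No plateau/offset term is included ("single
exponential" taken literally). The Michaelis–Menten fit starts from
V_max ≈ max(v) and K_m ≈ the substrate concentration at half-max by
interpolation, with non-negativity bounds; a fitted K_m outside
[min(S)/5, 5·max(S)] is flagged weakly identified (the saturated-design
case). Optional bootstrap standard errors resample points with
replacement under a seeded generator. Test oracles are independent 2-D
grid searches over the parameter plane; the fits must reach SSE within 1%
of the grid optimum.

Simulated assay designs: chases sample {0, 2, 4, 7, 10, 15, 20, 30} min —
about four half-lives of a 7-minute species, the standard design for such
a chase; enzyme datasets sample S = {1, 2.5, 5, 10, 25} µM around
K_m = 5 µM (0.2–5 × K_m). At 5% multiplicative noise the median relative
error is ~3.4% for t½ and ~3% for V_max.

## Problem sizes and determinism

Recovery checks run on populations of 500 cells (≈ 2100² px scenes),
segmentation accuracy on 100 cells, enrichment statistics on 1000–3168
cells across 20 seeds, and kinetic recovery on 100 replicate fits —
sizes at which binomial uncertainty on the recovered rates is a few
percent and a full run completes in minutes. Every stochastic step takes
an explicit seed; identical config + seed reproduce every output file
byte-for-byte (the manifest records SHA-256 checksums).

## Known limitations

- Straight-rod geometry only; no curvature, no 3-D, no time-lapse
  tracking or photobleaching.
- The phase-like channel is an idealized body stain; segmentation
  parameters are not tuned for real phase-contrast artifacts.
- One reporter channel is rendered per scene; analyses needing two
  simultaneous reporters must run two scenes sharing a geometry seed.
- The compartmentalization thresholds (ρ = 2, 0.5) are conventions chosen
  for separability on the generator's conditions, not biological
  constants; on real data they should be calibrated against controls.
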