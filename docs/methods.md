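# Methods

This note documents the models and procedures implemented in `asymdiv`,
the defaults they ship with, and what the synthetic benchmarks do and do
not establish about real data.

## Coordinate conventions

All images are held as `(t, c, z, y, x)` arrays with 0-based voxel
indices and half-open region bounds.  Physical positions are micrometres
with the origin at the centre of voxel (0, 0, 0).  The few-second lag
between sequentially scanned channels is ignored: all channels of one
time index are treated as simultaneous.

## Registration model

The two centrosomes define the cell's anterior–posterior axis.  Per
frame, the anterior centrosome maps to normalized coordinate *s* = 0 and
the posterior one to *s* = 1; any point projects to
*s* = (p − c_ant)·û / |c_post − c_ant|, discarding the perpendicular
component.  Raw *s* is kept unclamped — an endosome beyond a centrosome
yields *s* < 0 or > 1 — and clamping to [0, 1] happens only at histogram
binning, so no information is silently destroyed upstream.

Axis *polarity* is anatomical and cannot be inferred from the image, so
anterior/posterior assignment requires an explicit direction vector in
the annotations; the pair's identity is kept consistent across frames by
nearest-neighbour matching and the label never flips mid-movie.  Frames
with a missed centrosome pair are filled by linear interpolation.

Temporal registration sets T = 0 at anaphase onset, operationally the
first appearance of the cleavage furrow: the mean membrane intensity in
a 0.5-µm slab through the centrosome midpoint, perpendicular to the
axis, must exceed twice its baseline (median of the first quartile of
frames) for at least two consecutive frames.  A manual annotation
overrides detection.  Analysis windows are expressed in frames around
T = 0 (default ±20 frames, i.e. ±4 min at the default 12-s interval).

## Detection and tracking

Detection is scale-normalized Laplacian-of-Gaussian filtering, 3×3(×3)
local maxima above a score threshold, greedy non-maximum suppression at
a minimum physical separation, and sub-pixel refinement by a 3-point
quadratic fit per axis (offsets clipped to ±0.5 voxel).  A detection σ
below one voxel is refused with advice to resample.  Tracking runs on
2-D maximum-intensity projections by default, matching the analysis
substrate of the kymograph and asymmetry readouts; 3-D mode exists.

Linking is greedy: direct (gap 1) candidate pairs are assigned in
ascending distance, capped at `max_disp_um`; surviving spots may then
close gaps up to `max_gap_frames`, with the cap scaled by the gap
length.  Ties break deterministically on (track id, spot index).  Greedy
linking is deterministic and adequate at the endosome densities this
pipeline targets; the test suite carries a brute-force assignment oracle
that quantifies its gap to optimal matching on small instances.

Defaults (endosome channel): σ = 0.25 µm, score ≥ 5, NMS separation
0.3 µm, max displacement 1.0 µm/frame, gap ≤ 1 frame.  These follow from
the simulator's motion scale (steps ≲ 0.3 µm/frame) and are exposed in
the API and CLI.

## Kinematic readouts

- **Kymograph**: per frame in [t0 − W, t0 + W] (W = 20), the clamped *s*
  values of all tracked endosomes are histogrammed into B = 50 equal
  bins and normalized by the endosome count, so each occupied row is a
  probability distribution (rows with no endosomes are zero).
- **Telophase position**: mean clamped *s* at the frame nearest a query
  time (default T = +4 min).
- **Velocity**: one step's speed is the Euclidean displacement between
  consecutive observed spots divided by elapsed time (gap steps span
  multiple intervals); the per-cell value averages over all steps of all
  tracks in the window (per-track averaging available by flag).  Speeds
  are unsigned, in µm/min; the signed axial component is reported
  alongside, keeping motility and directionality separable.
- **Asymmetry index**: daughters are delimited by the plane through the
  centrosome midpoint perpendicular to the axis (a membrane-derived mask
  can be plugged in, but the midplane is deterministic and testable);
  pixels exactly on the plane are shared half-half so that axis reversal
  maps X to −X exactly.  Background is subtracted as the mean of a
  sample-free blank region, with negatives clipped.  Classification uses
  non-strict thresholds: X ≥ 0.2 posterior, X ≤ −0.2 anterior, else
  symmetric — the boundary case counts as asymmetric.

## Colocalization

Manders coefficients are computed in their thresholded form: M1 is the
fraction of channel-1 intensity *above its threshold* residing in pixels
where channel 2 is also above its threshold (the unthresholded variant
is a flag).  Thresholds come from a blank region (mean + 3 SD, factor
configurable) or from the Costes procedure: orthogonal (total-least-
squares) regression ch2 = a·ch1 + b, then T1 descends from the intensity
maximum in steps of one quantization unit (1 for integer data, range/255
for floats) with T2 = a·T1 + b, until the correlation of pixels below
both thresholds reaches ≤ 0; the last pair before crossing is returned,
and a never-crossing (globally correlated) image returns minimum
thresholds with a flag.  When both blank and Costes thresholds are
requested, Costes takes precedence and both are reported.

Significance uses Costes block randomization: channel 2 is tiled into
blocks (default 5 px, at least the PSF extent; edge tiles are excluded
so permutation is well defined), tiles are permuted n times, and
p = (1 + #{r_rand ≥ r_obs}) / (n + 1) — the add-one estimator avoids
p = 0.  Under independent channels the test is calibrated (rejection
rate ≈ α, verified at α = 0.05 over 200 replicates).

The central analysis zone between the anaphase nuclei is a rectangle of
fixed physical size — 50 × 100 px at 0.126 µm/px, i.e. 6.3 × 12.6 µm —
centred on the centrosome midpoint with the long side along the axis,
rescaled to the image's pixel size and clipped to the inter-nuclear gap.

## Fixed-cell composition

Nuclei: Otsu threshold on the smoothed DAPI MIP, two largest components,
ordered along the A-P direction.  In fixed cells the nucleus centroids
anchor the axis (*s* = 0 anterior, 1 posterior).  Endosomes: the
reference-channel MIP is rescaled to 8-bit by percentile scaling
(0.1–99.9 % → 0–255; the display scaling of the original protocol is
device-dependent, so a reproducible surrogate is used, with the bounds
as config keys), thresholded at the fixed value 100, and connected
components below 4 px are dropped; touching endosomes merge (no
watershed).  Zones: *central* iff the centroid's *s* lies strictly
between the inner nucleus edges; otherwise the side of the gap midpoint
decides; the surround zones include the nuclear footprints (only the
central zone is exclusive), which is flagged in output metadata.

A marker is *present* on an endosome when its above-threshold area
covers at least 10 % of the endosome footprint — an overlap-fraction
rule rather than ≥1 px, robust to PSF bleed.  Cargo metrics: mean cargo
intensity over the footprint normalized to the mean DAPI over the
nuclear mask, and the fraction of each marker-demarcated footprint
occupied by above-threshold cargo (channel-independent).  Division
orientation: the plane–surface angle is 90° minus the angle between the
cleavage-plane and surface normals, folded into [0°, 90°], classified
into [0, 30) / [30, 60) / [60, 90].

## Statistics

Pearson chi-square without continuity correction (df = (R−1)(C−1));
two-tailed unpaired Student t-test with pooled variance by default
(Welch by flag) — matching common graphing-software defaults; OLS
regression reporting R², F = (n−2)·R²/(1−R²) and Sy.x = √(SSE/(n−2)).
No multiple-testing correction is applied by default; Bonferroni and
Benjamini–Hochberg adjusters exist but are off.  The report writer
produces byte-deterministic CSV/JSON bundles plus a manifest (config
hash, seed, version, inputs); a missing stage is recorded and raises.

## The synthetic generator: what it emulates

The division simulator renders a three-channel movie (membrane,
centrosome, endosome) of an elliptical cell whose two centrosomes
separate linearly along a configured A-P direction, with a furrow signal
appearing exactly at the configured anaphase frame (ramping over 3
frames, abscission after 10) — anaphase onset is thus an unambiguous
detection target.  Endosome motion is a two-regime 2-D random walk:
before anaphase, drift at the centripetal rate toward a central zone of
radius `central_zone_radius_um` (free diffusion inside it); from
anaphase on, each step's axial component is +v_d·Δt with probability
`p_bias` and −v_d·Δt otherwise, plus isotropic Gaussian steps, with
reflection at the cell boundary and, after abscission, at the cleavage
midplane.  Rendering draws Gaussian spots (PSF σ) into a thin z-stack,
then applies Poisson noise and additive Gaussian read noise.  Identical
seeds give bit-identical movies.

Key defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| frame interval | 12 s | the live-imaging cadence the readouts assume |
| frames / t0 | 41 / 20 | covers the ±20-frame (±4 min) analysis window |
| pixel / z-step | 0.2 µm / 1 µm, 3 planes | 40× water-immersion live-imaging scale; thin z because analysis runs on MIPs |
| cell semi-axes | 7 × 5.5 µm | progenitor cell-body scale |
| endosomes | 12 | a resolvable density for the tracking contract; real cells can carry more |
| centripetal rate | 0.02 µm/s (1.2 µm/min) | convergence into the central zone within the pre-anaphase window, at the µm/min speeds endosomes show |
| central zone radius | 3 µm | matches the ~6 µm-wide inter-nuclear zone |
| v_d | 0.02 µm/s (1.2 µm/min) | post-anaphase directed-transport speed scale |
| p_bias | 0.8 | clearly polarized but not deterministic motion |
| step σ | 0.05 µm/frame | sub-pixel diffusive jitter |
| PSF σ | 0.2 µm lateral | spinning-disk confocal at high NA |
| noise | Poisson + Gaussian σ=2 | standard photon + camera noise model |

The fixed-cell generator places soft-edged disks (compact support) of
requested marker combinations into requested zones with a minimum
mutual separation, renders DAPI nuclei as two soft ellipsoids, and
applies the same noise model.

**What passing the synthetic benchmarks does not show.**  The generator
has no photobleaching, stage drift, optical aberrations, membrane
mechanics, endosome fusion/fission, or marker-expression variability;
spots are ideal Gaussians/disks and the background is spatially flat.
Recovery results on it therefore validate the *algorithms* (detection,
linking, registration, the index, the category calls) under a known
model, not the biological accuracy of any specific real-data analysis —
on real movies, densities above ~1 endosome per µm² in the converged
zone, uneven background, or furrow-signal ambiguity will degrade
performance in ways these tests do not measure.

## Numerical choices

- Butterworth denoising uses the transfer function
  1/(1 + (f/fc)^(2·order)) per 2-D plane with DC gain exactly 1 (mean
  preserved); it is optional preprocessing with user-set cutoff — no
  self-supervised calibration.
- Background subtraction is order-configurable around the MIP; the
  default applies it after projection.
- Sub-pixel offsets are clipped to ±0.5 voxel; border maxima get no
  refinement.
- The Costes scan skips candidate thresholds whose below-threshold pixel
  set is too small or constant (correlation undefined) rather than
  terminating on them.
- Degenerate inputs raise typed errors (`MissingCalibrationError`,
  `DegenerateGeometryError`, …) rather than returning sentinels.

## Known limitations

- Greedy linking can swap identities when two endosomes pass within the
  per-frame displacement cap of each other; no motion model is used.
- Merged (sub-resolution) endosome pairs segment and track as one
  object; no watershed or deconvolution is attempted.
- The daughter boundary is the centrosome midplane, not the actual
  furrow membrane; cells whose furrow is displaced from the midpoint
  will bias X slightly.
- The central-zone rectangle assumes the A-P axis is near-aligned with
  an image axis (true for the simulator; rotated acquisitions should be
  rotated first).
- Out-of-range *s* values are retained but all histogram-based readouts
  clamp them to [0, 1].
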