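# Methods

## Problem

On projection-resolved OCT angiography (PR-OCTA) the inner retina carries
four capillary plexuses: the nerve-fiber-layer plexus (NFLP), the
ganglion-cell-layer plexus (GCLP), the intermediate capillary plexus (ICP)
and the deep capillary plexus (DCP).  The GCLP and ICP do not respect
anatomic layer boundaries — the GCLP occupies the GCL and the anterior
inner plexiform layer, the ICP straddles the IPL/INL border — so the
posterior GCLP boundary must be located functionally, as the depth of
minimum vessel density (the vascular watershed) inside the combined
GCL+IPL slab (GCIPL).  This package implements that localization and the
downstream GCLP/SVC slab metrics, and ships a synthetic OCTA phantom
generator so the whole pipeline is testable without clinical scans.

## Pipeline

1. **Projection resolution.**  Flow signal under a vessel is partly
   replicated at deeper depths ("tail" artifacts).  We suppress tails by
   strict axial-peak retention: walking down each A-line, a voxel keeps its
   flow only if it strictly exceeds the running maximum of all shallower
   flow; suppressed voxels are clamped to `min(flow, floor)` with
   `floor = 0` by default.  A tail can never exceed its own source, so pure
   tails vanish; an in-situ deeper vessel that rises above everything over
   it is kept in place.  The rule is idempotent and never increases flow.
   Ties are suppressed: a tail can equal its source only through noise.

2. **Vessel density (VD).**  Per slab, the en face angiogram is the maximum
   flow projection over voxels whose centers fall in the half-open depth
   interval `[top_z, bottom_z)`.  A reflectance reference map (mean
   structural signal in a 120 µm slab under the IPL/INL surface) drives a
   linear adaptive threshold, `thr = offset + slope · ref`, which
   compensates signal-strength variation: scaling structure and flow
   jointly leaves the vessel mask unchanged when `offset = 0`.  The binary
   mask (strictly greater-than; ties to background) is low-pass averaged
   (7 px square kernel, ≈ 105 µm at the 400-A-line scan scale) into a VD
   map.  Pixels whose reference falls below a cutoff are excluded from all
   regional averages (floater shadows, vignetting).

3. **Sectors.**  A polar grid centered on the foveal avascular zone: annuli
   of 0.5 mm, 16 angular slices of 22.5°, the central 1-mm-diameter circle
   excluded (plexuses merge near the FAZ).  Angle runs from the temporal
   horizontal, counter-clockwise in right-eye orientation; quadrants are
   four contiguous slices centered on each principal axis; radial and
   angular bins are half-open with ties to the lower bin.  Rings beyond the
   inscribed circle are flagged partial and excluded from cohort means
   (corner signal is the least reliable part of the scan).  The FAZ center
   is the centroid of the largest connected component with VD < 0.05 inside
   the central 1.5 mm box, falling back to the scan center.

4. **Depth profiles and the watershed.**  The GCIPL is divided into 20
   equal depth-fraction sub-slabs; each yields an angiogram binarized with
   the one shared threshold map, a VD map, and sector means — a 20-point VD
   profile per sector with abscissae at the sub-slab centers
   `(i + 0.5)/20`.  Profiles are fitted with a sixth-degree polynomial by
   ordinary least squares.  Extrema are the real derivative roots within
   the data-supported fraction range.  Each fitted local minimum is scored
   by topographic prominence — the lesser of the rise to the best anterior
   fitted peak and the rise of the curve posterior to it (the posterior
   side may be truncated by the IPL/INL border, where the ICP lives) — and
   the most prominent minimum is the watershed trough; the peak is the
   largest anterior maximum.  Two guards reject artifacts of least-squares
   oscillation: the winning prominence must reach 2 % of the fitted range,
   and the *raw* profile must rise posterior to the trough by at least 5 %
   of its range (otherwise the profile is single-plexus and no watershed
   exists).  A dense 10⁻³-step grid evaluation cross-checks every analytic
   trough.  Both the fitted trough and the raw
   interior minimum are reported; the fitted value is canonical.  Per-eye
   estimates use the area-weighted aggregate profile over full rings;
   quadrant results pool sector points per quadrant and also report the
   mean ± SD of per-sector extrema.

5. **Slabs and cohort statistics.**  The derived boundary defines
   GCLP = NFL/GCL → 75 % GCIPL and SVC = ILM → 75 % GCIPL; GCC, GCIPL and
   NFL slabs are anchored the obvious way.  The 80 %-GCC rule is compared
   with 75 %-GCIPL via the closed form
   `diff(µm) = 0.05·GCIPL − 0.2·NFL`, so the 80 %-GCC boundary is shallower
   exactly where `NFL > GCIPL/4` (thick nasal wedge).  Cohort statistics
   run on sector means: squared Pearson correlation of GCLP VD against
   NFL/GCIPL/GCC thickness; two-sided paired t for the with/without-PR
   comparison; repeatability as the within-subject coefficient of variation
   `CV = sqrt(mean(d²/2)) / grand mean` over paired repeat scans
   (Bland–Altman convention); population mean/SD maps with left eyes
   mirrored into right-eye orientation.  Significance of correlation
   differences uses a fixed-seed bootstrap over sectors (2000 resamples),
   since no parametric form is obvious for dependent r² values.

## Phantom generator

The generator emulates what the analysis relies on, not retinal optics.

* **Geometry.**  6 × 6 mm field, 400 × 400 A-lines by default (tests and
  recovery experiments use 200 × 200 × 320 voxels to keep runtimes in
  minutes), 3 µm axial voxels.  Surfaces: a Gaussian foveal pit; NFL
  thickness growing radially with a nasal cosine wedge (≈ 10–45 µm at the
  field edge, ~0 at the fovea); GCIPL thickest in a parafoveal annulus
  (≈ 95 µm) and thinned at the pit.  Reflectance stack: bright NFL (1.0),
  dim GCL (0.45), bright IPL (0.8), dim INL (0.35), OPL/ONL/deep layers
  below; multiplicative Gaussian speckle (SD 0.2).

* **Vessels.**  Each plexus is a population of short capillary segments
  (0.15–0.40 mm, 1 px tube radius, one voxel axially) with center depths
  drawn from a ±3σ-truncated Gaussian in layer-fraction coordinates:
  NFLP at 0.6 of the NFL span (arcuate orientation, density scaled by NFL
  thickness, absent where NFL < 18 µm), GCLP at 0.35 ± 0.19 of the GCIPL,
  ICP at 1.02 ± 0.10 (straddling the IPL/INL border), DCP at 1.45.  Areal
  fractions (0.35/0.50/0.42/0.42) are set so slab-level VD lands in the
  tens of percent, the regime the method operates in clinically.  No
  vessels inside the 0.5 mm FAZ radius.  Flow amplitude bands are staggered
  with depth (NFLP 0.72–0.78 … DCP 1.02–1.08) and increase with depth
  within each plexus, so decorrelation is effectively monotone with depth
  per A-line — the regime in which strict axial-peak retention keeps
  in-situ deeper vessels.  This is a deliberate idealization: pure
  running-max retention cannot keep a deeper vessel that is dimmer than
  anything above it, and the commercial algorithm's handling of that case
  is not public.

* **Ground truth.**  The planted GCLP/ICP axial density (areal-fraction-
  weighted mixture of the two truncated Gaussians) is brute-force minimized
  on a 10⁻³ grid between the plexus centers; the minimizer is stored as the
  eye's true watershed fraction.  A scene with one plexus (or overlapping
  supports leaving no interior minimum) has no watershed truth and raises
  unless explicitly allowed.  `config_for_watershed(target)` places the
  GCLP 0.35 below the target (σ = 0.17) and solves the mixture
  stationarity condition for the ICP offset so the planted minimum sits
  exactly on the target while the GCLP bump keeps its realistic dominance.

* **Tails and noise.**  Tails follow `tail[z] = decay · (clean[z−1] +
  tail[z−1])` with decay 0.9 per 3 µm voxel (half-depth ≈ 20 µm), so
  projection artifacts persist through the inner retina as they do in real
  scans; flow noise is uniform on [0, 0.015].  Repeat scans share the
  vascular scene and differ only in the noise realization.

* **Cohorts.**  Per-eye multiplicative jitter on thicknesses (SD 6 %) and
  plexus areal fractions (SD 5 %); eyes alternate OD/OS and left eyes are
  stored mirrored, with the analysis mirroring them back on entry.

* **What the phantom does not model** — and hence what passing tests do
  not show about real data: optical speckle statistics and interferometric
  noise, eye motion, vascular trees and flow heterogeneity, pathology,
  segmentation error in the input surfaces, and any systematic difference
  between SSADA decorrelation and the staggered amplitude model.  The
  phantom validates the *pipeline logic* (geometry, suppression rule,
  thresholding, fitting, statistics), not clinical performance.

## Defaults worth knowing

| parameter | default | why |
|---|---|---|
| axial voxel | 3 µm | clinical SD-OCT scale; the acquisition depth scale is configurable |
| tail decay | 0.9 / voxel | tails persist ~100 µm, matching their clinical visibility in depth |
| threshold slope/offset | 1.16 / 0.03 | offset ≈ twice the phantom noise floor; slope puts the threshold at ≈ 0.5 for unshadowed reflectance (≈ 0.40 in the reference slab) |
| low-pass kernel | 7 px | ≈ 105 µm at 15 µm/px; the smallest kernel that stabilizes sector means |
| low-signal cutoff | 0.12 | ≈ 30 % of normal reference reflectance; flags ≥ 70 % shadowing |
| sub-slabs | 20 | depth resolution 5 % of GCIPL; half a sub-slab (0.025) is the recovery error budget |
| polynomial degree | 6 | lowest degree representing two bumps and one valley with stable extrema |
| FAZ cutoff | VD < 0.05 | isolates the truly avascular core; higher cutoffs merge noisy low-VD blobs |

## Numerical choices and degenerate inputs

* Fractional surface depths; voxel-center, half-open slab inclusion —
  sub-slabs tile the GCIPL exactly, so the 20-sub-slab union reproduces the
  whole-slab projection.
* Constant profiles fit with R² flagged 0 and no watershed; zero-variance
  paired differences raise instead of returning an infinite t; empty
  regions after exclusion raise a missing-data error; sectors with every
  pixel excluded are flagged missing and skipped by aggregation.
* OS data are mirrored along the nasal/temporal axis on entry; mirroring
  is involutive and commutes with quadrant labels (temporal ↔ nasal).
* All randomness flows from `numpy.random.default_rng` seeded by the
  caller; the full pipeline is bit-reproducible for a fixed seed.

## Known limitations

* The projection-suppression rule is a defined stand-in for the commercial
  PR-OCTA algorithm, whose exact suppression and noise handling are not
  public; with/without-PR comparisons are qualitative matches only.
* The polynomial watershed carries a representation bias of up to ~0.02
  GCIPL fraction for profile shapes whose ICP bump is mostly posterior to
  the IPL/INL border; this is inherent to the stated degree-6/20-point
  method and is why the recovery budget is half a sub-slab.
* Whether slab membership should be voxel-center or partial-volume
  weighted is unstated in the underlying protocol; voxel-center was chosen
  for exact tiling.
* Real-cohort numbers (e.g. population VD levels and their CVs) depend on
  scanner physics the phantom does not model; the package reproduces the
  structure of those analyses, not their clinical values.  In particular,
  phantom repeat scans share the vascular scene *and* the segmented
  surfaces, so thickness repeatability CVs are zero by construction and VD
  CVs reflect only the flow noise floor — far below clinical repeat
  variability, which includes refixation and re-segmentation.
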