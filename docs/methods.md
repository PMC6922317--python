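# Methods

## Dry-mass calibration

All mass quantities derive from the linear relation between refractive
index and dry-mass concentration, ρ = (n − n_m)/α, with the medium RI
n_m = 1.33 and the specific refractive increment α = 0.19 mL/g
(numerically 0.19 µm³/pg).  α for protein/lipid mixtures falls in
0.18–0.20 mL/g; 0.19 is the midpoint and is configurable everywhere
(`CalibrationModel`).  Measurements with mean RI below n_m (possible for
noisy near-background objects) are clipped to zero density with a warning
rather than reported as negative mass.

## Organelle pipeline (projections + fixed threshold)

A 3D volume is reduced to a 2D map by maximum-intensity projection; RI
images are quantitative, so objects are segmented by a *fixed absolute*
threshold rather than an automatic one: 1.354 for lipid droplets (LDs),
1.347 for the lipid-laden late endosomes induced by U18666A.  Connected
components (8-connectivity, the convention of primary-object detection in
CellProfiler-style pipelines) are gated on the equivalent diameter — the
diameter of the circle with the component's area — at 1–7 px for LDs and
1–3 px for endosomes.  Touching objects are *not* declumped; they merge
into one component (limitation, see below).  Mean RI is measured on the
unmodified projection; the object is treated as a sphere of the equivalent
diameter for volume and mass.  Coordinates are 0-based (row, column) =
(y, x); a pixel's centre sits at ((i + 0.5)·Δ) µm.

Population analytics (`drymass`): per-frame count, total and mean mass;
fluxes are per-interval differences of the 5-frame centred moving average
of the mass traces, divided by the frame interval.  The interval
representation makes the cumulative sum of flux × interval reconstruct the
smoothed trace exactly, which is the invariant the tests check.  The
5-frame window suppresses single-frame segmentation jitter without
distorting transitions slower than ~10 min.

Two headline estimators deserve comment because naive versions fail at
small population sizes (a handful of objects per frame):

* **Steady per-object flux** — the median of the per-object flux over the
  second half of the run (after the count plateau), robust to birth events
  and single-frame jitter.
* **Flux zero-crossing time** — over a linear flux ramp the mean
  per-object mass trace is quadratic in time, so the crossing is the
  vertex of a count-weighted quadratic fit of the mean-mass trace over the
  transition window (default: the first 55 min, covering the ramp plus
  margin; weights ∝ √count since the mean's variance scales as 1/count).
  A pointwise sign change of the differentiated trace is unusable at 3–9
  objects: every birth perturbs the mean by that object's individual
  discretisation factor, which is the same order as the mass dip itself.

The molecule converter `oa_molecules_per_minute` uses the oleic-acid molar
mass 282.46 g/mol; 1×10⁻⁴ pg/min corresponds to ≈ 2.1×10⁵ molecules/min.

## Whole-cell segmentation, 3D extension and tracking

Projected maps are clip-rescaled so that RI 1.32 → 0 and 1.34 → 1;
intracellular extremes (nucleoli, LDs) saturate at 1 and stop influencing
the cell-scale detection.  After Gaussian smoothing (σ = 2 px), seed blobs
are pixels ≥ 0.95, gated to the expected cell equivalent-diameter window
(80–250 px at 0.18 µm/px) and shrunk to their inner half (distance
transform ≥ half its maximum) so seeds are strictly interior.  Foreground
is smoothed rescaled value ≥ 0.89.  The published description of the
underlying propagation algorithm does not print its exact functional, so
it is implemented as regularised geodesic competition: each foreground
pixel joins the seed with the cheapest 8-connected path, a step costing
its Euclidean length (1 or √2 px) plus λ·|image difference| with
λ = 0.05.  Ties break to the lowest seed label; the partition equals
multi-source Dijkstra with the same cost (tested against an independent
heap-based oracle).  λ → 0 reduces to the geodesic nearest-seed (Voronoi)
partition on uniform foreground; large λ locks boundaries onto image
ridges.

Two genuinely open readings are exposed as configuration:
`threshold_orientation` (default `direct`: foreground = rescaled ≥ 0.89;
`inverted` provided for data where cells are darker than the background)
and the size gate interpreted as *diameters* (CellProfiler's "typical
diameter" convention) rather than areas — both switchable on
`CellSegParams`.

3D extension: a voxel belongs to cell c iff it sits under c's 2D footprint
and its RI lies in [min, max] of the RI observed under c's 2D mask,
expanded by 1×10⁻³.  The expansion covers the *two-sided* noise
distribution of boundary voxels (~2 × the RI noise scale); expanding by
only one noise s.d. systematically excludes half the fluctuating boundary
shell and biases small rounded cells ~10% low.

Tracking: greedy maximum-IoU matching between consecutive frames;
matches below IoU 0.3 start new tracks.  Division takes precedence over
continuation: a previous object overlapping ≥ 2 current objects, each at
IoU ≥ 0.15, spawns two new tracks with the parent recorded as lineage
parent.  Every current object receives exactly one track id.

## Rotation quantification

Adjacent projected frames are contrast-normalised (1st–99th percentile
window — float RI maps need a defined dynamic range for gradient-based
descriptors), SIFT keypoints are detected and matched with Lowe's ratio
test (ratio 0.75, the canonical value; cross-check enabled); pairs with
fewer than 10 accepted matches are recorded as failures, never as zero
rotation.  A homography H (frame t → t+1) is fitted by RANSAC (4-point
samples, 3 px reprojection tolerance, seeded generator, least-squares
refinement on the consensus inliers; collinear source geometries are
rejected).  The rotation angle is θ = atan2(H₁₀, H₀₀) of the upper-left
2×2 block — the similarity interpretation, exact for rigid in-plane
motion and invariant to uniform scale and translation; a non-positive
block determinant (reflection) is an error.  Sign convention:
counter-clockwise positive in image coordinates with y pointing down.
Angles are accumulated *signed* (direction reversals are a real feature of
the phenomenon); per-interval angles live in (−180°, 180°], so the frame
rate must oversample the rotation — at the fastest observed speeds
(~13°/min) one frame per minute is ample.  Rose histograms bin the
per-interval angles (bin width must divide 360°).

## Fluorescence cross-validation

`ks_bootstrap`: for each fluorescence-threshold quantile, the observed
statistic is the two-sample KS distance between RI values under the mask
and under the whole cell; the null is *mask-level* resampling — random
pixel sets of the same size drawn within the cell (the "random object"
null) — with the +1-corrected p-value (k+1)/(B+1), which is uniform on a
grid under the null (verified by a calibration test at B = 500).  The
resampling unit (masks, not pixels or whole objects) is a documented
choice; object-preserving nulls would require segmenting the fluorescence
channel first.  `overlap_fraction` reports |a∩b|/|a| plus the symmetric
variants (|a∩b|/|b|, Jaccard).  Fluorescence masks are thresholded at
half-maximum above background (midpoint of the 1st/99.9th-percentile
window), which localises the boundary of a symmetric PSF accurately.

## The phantom generator

Scenes are analytic solids — spheroids, substrate-clipped half-spheroid
domes, and capsule tubules — rasterised with partial-volume anti-aliasing:
voxels crossing a surface get their coverage fraction from a 3×3×3
sub-voxel grid, so the voxel-summed dry mass of a noiseless phantom
matches the analytic ground truth within ~1% (tested).  Additive Gaussian
RI noise defaults to σ = 5×10⁻⁴, slightly above the instrument's
theoretical sensitivity (2.71×10⁻⁴) so phantoms are at least as noisy as
real data.  All randomness derives from the spec seed; identical specs
give bit-identical volumes.  Default grid 128×128×32 at 0.18 µm lateral /
0.4 µm axial — a desk-scale stand-in for the instrument's 90×90×30 µm
field (the mitosis scenario uses 256×256 laterally to hold a 40 µm spread
cell).

Scenario defaults encode the study conditions as recovery targets:

* **oa_loading** (180 min, 1 frame/min): LD count 3 → 9 by minute 25 →
  48 at the minute-100 plateau (16-fold); all LDs share one mass
  trajectory whose flux ramps −1×10⁻⁴ → +1×10⁻⁴ pg/min over 50 min
  (zero at 25 min), so newly born LDs appear at the population-mean mass.
  Initial per-LD mass 0.012 pg (r ≈ 0.21 µm): nascent LDs start near the
  detection floor, making the scheduled dip a ~10% relative excursion —
  consistent with per-LD mass growing several-fold over the experiment.
  LD RI 1.39 (measured LD refractive indices are 1.38–1.42).
* **u18666a** (600 min, sampled every 10 min): endosome count 5 → 30
  (6-fold), per-object mass drifting +25% with a ±0.0006 pg, 90-min
  oscillation whose flux regularly turns negative (recycling continues
  under the drug); endosome RI 1.36, r ≈ 0.24 µm.
* **mitosis** (30 min, 2 frames/min): one dome-shaped cell grows
  5,000 → 6,000 µm³ (footprint ≤ 40 µm), rounds to 1,500 µm³ (footprint
  16 µm) and splits at minute 26 into two 750 µm³ daughters that respread.
  Cytoplasm RI 1.342, nucleus 1.345, nucleoli 1.352 — all above the
  rescaled 0.89 foreground cut.  Daughter footprints (8.2 µm) are chosen
  comfortably above the 80 px size gate, as the real daughters evidently
  were under the published gates.
* **rotation** (quasi-2D, 160×160×8): the nucleus + 3 nucleoli + 35 LDs +
  10 tubules rotate rigidly about the cell centre at a configurable speed
  (defaults cover the observed 0.2–13°/min range).  Frames are re-rendered
  analytically from the rotated ground-truth constellation rather than by
  image resampling — exact, with no compounding interpolation error — and
  the per-interval ground-truth angles sum exactly to the schedule.
* **static**: 12 LDs + 5 mitochondrial tubules (RI 1.38) for
  fluorescence/RI cross-validation; synthetic fluorescence renders each
  class's lateral footprint convolved with a Gaussian PSF whose FWHM is
  the fluorescence Abbe limit λ/(2NA) = 325 nm at 520 nm / NA 0.8, plus
  Poisson shot noise over a constant background.

What the phantom does *not* emulate — and hence what passing recovery
tests do and do not show: no wave-optics image formation (no tomographic
transfer function, no coherent noise, no missing-cone elongation), no
organelle shape irregularity or internal RI texture, no cell migration or
deformation during rotation, no LD–LD contact or fission, no z-drift.
Organelle lateral positions keep their natural sub-pixel diversity; this
is load-bearing, since the population-mean mass estimator relies on
sub-pixel dithering across objects to track the true mass smoothly (the
pixel-snapped alternative flattens the measured trace).  Recovery on the
phantom therefore validates the measurement chain and its estimators, not
robustness to instrument artefacts.

## Numerical choices and degenerate inputs

* Partial-volume supersampling 3×3×3; boundary bands located by a
  conservative half-voxel-diagonal margin in the solid's normalised
  coordinates.
* Per-frame noise streams come from independent seeded generators
  (seed, frame), so frames are reproducible in any access order.
* Propagation tie-break: lowest seed label at equal path cost; dijkstra
  distances compared directly (no tolerance), matching the oracle up to
  ties, which the tests exclude.
* Empty results are legal everywhere (zero seeds, empty masks, frames
  with no objects); frames whose analysis fails are logged and skipped,
  never silently zeroed.  Rotation-trace failures are NaN intervals with
  recorded reasons; the cumulative angle sums available intervals.
* TIFF I/O: volumes must be float-typed (integer exports lose the RI
  meaning and are rejected); missing spacing metadata falls back to
  configured values with a logged warning.  Measurement CSVs round-trip
  at better than 1e-9 relative.

## Problem sizes

The bundled validation runs use the desk-scale defaults above: 181 frames
of 128² × 32 voxels (LD scenario), 61 frames at one-tenth sampling
(endosome scenario), 61 frames of 256² × 32 (mitosis), 30–101 frames of
160² × 8 (rotation), and 500-resample bootstraps (colocalization) — sized
so the full recovery suite completes in minutes on a single CPU while
every headline statistic remains identifiable.

## Known limitations

* No declumping: touching organelles merge; counts are conservative in
  crowded fields.  The published pipelines' declumping settings are not
  stated, so none is implemented.
* The sphere model overestimates the volume of aspherical organelles.
* The 3D extension inherits any 2D footprint error along the whole z
  column; concave cell tops are handled only through the RI-range gate.
* Rotation estimation assumes in-plane rigid motion; out-of-plane nutation
  appears as scale/shear in H and is ignored by the angle extraction.
* IoU-threshold tracking can mislabel very fast movers (displacement
  comparable to the cell diameter per frame).
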