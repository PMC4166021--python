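# Methods

`debondmetry` measures what orthodontic debonding did to a tooth: how much
adhesive is left on the enamel and how much enamel came off with it.  The
input is a pair of triangle meshes of the same buccal surface — a pre-bond
*reference* scan and a post-debond *measured* scan, both in mm — and the
output is, per tooth, signed deviation statistics (heights of adhesive
remnants, depths of enamel loss), volumes, histograms, connected change
regions and adhesive remnant index (ARI) scores, plus cohort summaries over
a set of teeth.

## Pipeline

1. **Superimposition.** The measured mesh is rigidly aligned to the
   reference.  Initialization is centroid + principal-axes matching (the
   four sign-consistent axis assignments scored by nearest-neighbor RMS);
   refinement is trimmed iterative closest point: measured vertices are
   paired with their *exact* closest points on the reference surface
   (point-to-triangle, via a KD-tree on triangle centroids with a
   provable-exactness escalation), the largest-distance `trim_fraction` of
   pairs is discarded, and the optimal rigid motion of the retained pairs
   is solved in closed form (SVD/Kabsch).  Trimming exists because the
   bonded footprint genuinely changed shape: the region under study must
   not drive the fit.  `run_tooth` then makes a second pass in which every
   vertex flagged as changed by the first pass (|deviation| > noise floor,
   dilated 3 rings) is excluded and the pose is re-fit with minimal
   trimming (5%).  A known bonded-footprint polygon can be supplied as an
   explicit exclusion mask instead.

   Registration accuracy on phantoms is limited not by the solver but by
   the flatness of the cost valley: a measured vertex's distance to a
   faceted surface is insensitive to tangential slide (quartic, not
   quadratic, near the optimum), so poses settle within ~10⁻³ mm of truth
   rather than machine precision.  This matters only for quantities that
   integrate small signed deviations over large areas, which is why the
   region-volume estimator below detrends a residual background.

2. **Deviation field.** Every measured vertex is compared with the
   reference: deviation = exact distance to the closest reference point,
   signed by the side of the outward surface normal (barycentrically
   interpolated at the closest point).  Positive = material above the
   original enamel (remnant); negative = missing material (loss).
   Vertices whose closest point lies on the reference boundary, or farther
   than `max_distance` (default 2 mm), are invalid.

3. **Labeling.** Scanner precision is 2 μm, so deviations below
   `noise_floor = 0.002 mm` are not interpretable as real change.  Two
   modes:
   * *soft* (default, "table parity"): every valid vertex is labeled by
     sign; sub-precision magnitudes are only flagged.  Per-tooth minima of
     order 10⁻⁷ mm in published tables can only arise this way, so this is
     the mode whose statistics mirror such tables.
   * *hard*: |deviation| ≤ noise_floor ⇒ unchanged.  Used for region
     extraction and ARI area fractions.

4. **Statistics and volumes.** Per side (remnant/loss): mean/SD/max/min of
   deviation magnitudes (sample SD by default; configurable) and a
   prism-rule volume: Σ over faces of footprint area × mean side-clamped
   deviation of the face's corners.  The *footprint* area is computed from
   the per-vertex closest points on the reference rather than from the
   displaced measured triangle: for near-parallel surfaces the two agree,
   but on steep feature flanks the measured-face area is inflated by the
   slope factor √(1+|∇h|²) (≈ +5–10% for realistic bumps), which would
   bias volumes; the projected area integrates the height field over the
   reference surface, which is the quantity the volume is defined as.

5. **Regions.** Hard-labeled vertices are grouped into edge-connected
   components per side; components smaller than `min_region_area`
   (default 0.2 mm², ~80 vertices at the default 0.05 mm pitch) are
   dropped.  At the 2 μm noise floor about 21% of pristine vertices exceed
   the threshold, but their clusters are tiny (subcritical site
   percolation; the threshold sits well below the ~0.5 site-percolation
   threshold of a triangulated grid), so the area filter removes speckle
   without touching physical features.

   Each region's reported `volume` is estimated in three steps chosen to
   be unbiased under noise:
   * the core is dilated ring by ring while the ring's area-weighted mean
     signed deviation exceeds half its own standard error (a feature
     tapers smoothly through the threshold, so its skirt carries real
     volume; the significance gate stops growth at the feature's true
     support instead of chasing one-sided noise fluctuations);
   * the *unclamped signed* deviation is integrated over that support —
     clamping at zero would rectify noise into a positive bias, whereas
     the signed noise terms average out;
   * a planar background a + b·x + c·y, fitted by least squares to the
     deviations of pristine surface (valid, ≥ 8 rings from any core), is
     subtracted.  A residual rigid misfit produces exactly such a field to
     first order, and integrating even a ~10⁻⁴ mm offset over a few mm²
     would otherwise be visible against small feature volumes.
   The side-clamped prism integral over the bare core is kept as
   `core_volume` (it is the simplest defensible rule, and the
   conservation/additivity identities hold for it exactly).

6. **ARI.** Årtun–Bergland (0–3) and Krell (1–5) classes from the remnant
   area fraction, Osorio as a percentage of the bracket-base area.  The
   area fraction uses the hard-labeled, area-filtered remnant regions; the
   denominator is the supplied footprint polygon's area or an explicit
   `base_area`.  The published class definitions leave boundaries open;
   the conventions fixed here are: fraction 0.5 → Årtun–Bergland 2;
   Krell: exactly 0.9 → 3, exactly 0.1 → 4.

7. **Cohorts.** `cohort_summary` aggregates per-tooth reports
   (median/mean/min/max volumes; range of per-tooth mean heights; global
   maxima).  Teeth with an empty side contribute volume 0 but are excluded
   from height means.  Median for even n = mean of the two central order
   statistics.  `summarize_table` computes the same aggregate directly
   from a printed per-tooth table (Mean, SD, Max, Min, Volume), which is
   how published cohort numbers are reproduced when no scans were
   deposited; the two reference tables shipped in `data/` are per-tooth
   statistics of 15 debonded human third molars.

## Synthetic phantoms

No scan data accompanies the study the reference tables come from, so the
pipeline is validated by parameter recovery on phantoms
(`debondmetry.phantom`):

* **Base surface**: a 10 × 8 mm convex patch (principal curvature radii
  12 and 20 mm — molar-crown scale), plus a seeded low-frequency
  undulation (≤ 0.1 mm, 5–20 mm wavelengths) that stands in for enamel
  macro-texture and makes the pose observable; triangulated at 0.05 mm
  pitch (~32k vertices, comparable to an optical scan of this field of
  view).
* **Features**: cosine bumps h(r) = (H/2)(1 + cos(πr/R)) for r < R,
  displacing vertices along local normals, positive (adhesive remnant) or
  negative (enamel gouge).  The profile has compact support and the
  closed-form volume H·R²·(π/2 − 2/π), so every phantom carries exact
  ground truth.  The radial coordinate is the 3-D chord distance on the
  undisplaced surface — within ~0.1% of geodesic at these curvatures.
  Amplitude caps (remnant ≤ 1.0 mm, gouge ≤ 0.3 mm) bracket the largest
  debonding changes on record (0.76 mm heights, 0.207 mm depths).
* **Bonded footprint**: the central 60% of the patch (6 × 5 mm by
  default); all features must lie inside it, as bonding is confined to
  the centre of the buccal surface.
* **Two scanning sessions**: the pre mesh gets one Gaussian noise
  realization along vertex normals (sd = `noise_sd`, default 0.002 mm =
  the scanner's stated precision); the post mesh gets the features, then
  a rigid misalignment, then an *independent* noise realization.
* **Randomized study conditions** (`sample_phantom_spec`): one or two
  remnants (H ∈ [0.05, 0.76] mm, R ∈ [0.9, 1.8] mm) and one gouge
  (H ∈ [0.04, 0.2] mm — the span of per-tooth maximum loss depths
  observed after molar-tube debonding — R ∈ [0.8, 1.2] mm), placed
  disjointly; misalignment 1–5° rotation, 0.5–2 mm translation (teeth
  were held in a silicone bed between sessions, so repositioning is
  small).  Feature discs cover < 30% of the patch, leaving trimmed ICP a
  clean majority.

What the phantoms do **not** emulate: enamel microtexture and perikymata,
scanner stripe/reflection artifacts, holes or partial coverage, non-rigid
deformation, and resin that infiltrated the etched enamel (invisible to
any surface scan).  Passing recovery tests therefore demonstrates the
correctness of the geometry and estimators under realistic noise and
misalignment — not robustness to every artifact of real scans.

## Numerical choices

* Closest-point queries are exact: k nearest centroids first, with a ball
  query whenever the certificate (k-th centroid distance ≥ best distance +
  max centroid-to-corner radius) fails; ties between equidistant triangles
  break to the lowest face index.
* STL input merges bit-identical duplicate vertices; binary PLY output is
  written with 64-bit coordinates so round-trips are exact.
* ICP stops when the retained-pair RMS improves by less than `tol`
  (default 10⁻⁶ mm) or after `max_iter` (100); non-convergence is reported
  in the result, not raised.  Correspondences are subsampled
  deterministically (even stride, default 5000 points; 12000 in the
  refinement pass).
* Histograms bin magnitudes on [0, max] with half-open bins (last bin
  closed), default width 0.02 mm; percentages sum to 100 by construction.
* Degenerate inputs fail loudly: empty meshes, collinear prealign input,
  all-pairs-trimmed ICP, empty deviation fields and empty histogram sides
  raise typed errors; an empty statistics side returns an explicit
  empty-side marker (absent values, never zeros).

## Problem sizes used in validation

The recovery suite runs 20 sampled phantoms in two arms (noise-free and
2 μm noise) at the default 0.05 mm pitch (~32k vertices, ~64k triangles
each); the volume oracle compares the prism integral of a reference bump
(H = 0.5, R = 1.5 mm) against its closed form and against 5 μm grid
quadrature; closest-point exactness is checked against exhaustive search
on ≤ 500-triangle meshes.  Observed recovery at these sizes: pose errors
of order 10⁻³ mm and 10⁻³ rad (well under the 5·10⁻³ acceptance bounds);
total remnant and loss volumes within 1% (noise-free) and 5% (noisy) of
analytic truth; remnant amplitudes within 5 μm (noise-free).

## Known limitations

* Registration accuracy saturates at the faceting scale (see above); at
  0.05 mm pitch, poses are reliable to ~10⁻³ mm, not better.
* The region-volume estimator assumes features are compact and separated
  by a few mesh rings; merged or annular features are measured as one
  region, and two features closer than the dilation clearance may clip
  each other's skirts.
* Soft-mode (table-parity) volumes include rectified noise over the whole
  valid surface (≈ 0.4·σ per unit area at noise level σ); they mirror
  what an unthresholded inspection-software export reports, and are not
  the estimator to compare against ground truth under noise — the region
  volumes are.
* ARI scores depend on the supplied base area; without a footprint
  polygon or `base_area` they are omitted.
* Units are assumed mm throughout; no unit metadata is read from files.
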