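# debondmetry

**3D quantitative analysis of adhesive remnants and enamel loss after
orthodontic debonding.**

When a bonded molar tube (or bracket) is removed at the end of orthodontic
treatment, the adhesive interface fractures unpredictably: composite resin
may stay on the tooth, and a layer of enamel may come off with the
adhesive.  Classical adhesive-remnant-index (ARI) scoring grades this by
eye, as an area fraction.  `debondmetry` instead measures it: given a 3D
optical scan of the buccal surface taken *before bonding* (the reference)
and one taken *after debonding* (the measured surface), it superimposes
the two, computes a signed per-point deviation field, and reports remnant
heights and volumes, enamel-loss depths and volumes, height/depth
histograms, connected change regions, and ARI scores — per tooth and
aggregated over a cohort.

The package is aimed at dental researchers doing in-vitro debonding
studies with optical scanners (structured light or laser) that export
standard triangle meshes (PLY/STL/OBJ, coordinates in mm).

## Method in brief

* **Superimposition**: trimmed iterative closest point.  Measured vertices
  are paired with exact closest points on the reference surface
  (point-to-triangle, spatial index), the largest-distance fraction of
  pairs (default 30%) is discarded so the changed bonded area cannot bias
  the fit, and the rigid motion minimizing Σ‖R·pᵢ + t − qᵢ‖² over retained
  pairs is solved in closed form (Kabsch/SVD).  A second pass excludes the
  detected change regions and polishes the pose.
* **Deviation field**: for every measured vertex, d = ±‖v − ĉ(v)‖ where
  ĉ(v) is the exact closest point on the reference and the sign follows
  the outward-normal side; d > 0 is adhesive remnant, d < 0 enamel loss.
* **Volumes**: prism rule between near-parallel surfaces,
  V = Σ_faces A_footprint · mean(d⁺) (resp. d⁻), with per-region
  refinements (support dilation, planar background detrending) that keep
  volume recovery unbiased at the scanner's 2 μm noise level.
* **ARI**: Årtun–Bergland (0–3), Krell (1–5), and Osorio (% of bracket
  base area), computed from the hard-thresholded remnant area.
* **Validation**: synthetic phantoms — curved buccal-surface patches with
  cosine-profile features whose volume has the closed form
  V = H·R²·(π/2 − 2/π) — give exact ground truth for end-to-end parameter
  recovery under realistic misalignment and scanner noise.

## Worked example

No scan pair at hand?  Simulate one.  The phantom generator produces a
pre/post mesh pair of a 10 × 8 mm buccal patch with known features,
a rigid repositioning between the two "scanning sessions", and 2 μm
scanner noise, together with its ground truth:

```bash
$ debondmetry simulate --seed 7 --out demo/
wrote pre.ply, post.ply, truth.json, spec.json to demo

$ debondmetry run --pre demo/pre.ply --post demo/post.ply \
                  --out demo/report.md --format markdown --tooth-id demo
$ cat demo/report.md
# Tooth demo

| side | Mean | SD | Max | Min | Volume |
| --- | --- | --- | --- | --- | --- |
| remnant | 0.05149 | 0.1276 | 0.6838 | 1.067e-07 | 2.235 |
| loss | 0.00607 | 0.02055 | 0.1993 | 1.333e-07 | 0.2299 |

regions: 2 remnant (2.168 mm³), 1 loss (0.1497 mm³)
```

Reading the numbers: this phantom carries two adhesive remnants (peak
heights 0.684 and 0.192 mm, true total volume 2.161 mm³) and one enamel
gouge (depth 0.197 mm, true volume 0.148 mm³), hidden behind a 2.6°/1.2 mm
misalignment and noise.  The pipeline finds exactly 2 remnant regions and
1 loss region; the denoised region volumes (2.168 and 0.150 mm³) recover
the truth to 0.3 and 0.9%, and the table row's Max column reproduces the
true peak height to under a micrometre.  The table-row statistics
(Mean/SD/Max/Min and the unthresholded volume) are *soft-mode* values:
every signed deviation counts, which is why Min is a physically
meaningless 10⁻⁷ mm — real change below the 2 μm scanner precision cannot
be distinguished from noise, so such vertices are flagged rather than
silently dropped.  JSON output (`--format json`) carries everything:
histograms, region totals, ARI (when a footprint or base area is
configured), and the registration diagnostics.

Cohort numbers come either from a directory of per-tooth reports
(`debondmetry summarize`) or directly from a printed per-tooth statistics
table (`debondmetry table-stats --table table1.csv`).  Two such reference
tables — adhesive remnants and enamel loss for 15 debonded human third
molars — ship with the package; on the remnant table, `table-stats`
reports a median volume of 0.988 mm³, a mean of 1.1 mm³, a volume range of
0.047–4.16 mm³ and a maximum remnant height of 0.76 mm.

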