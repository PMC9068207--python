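# Methods

## Problem setting

Double-marker immunofluorescence shows two cell populations — here CD8⁺
T cells (channel A) and NPMc⁺ leukemic cells (channel B) — and the
question is how much physical contact there is between them. A naive
pixel-colocalization number depends on magnification, exposure and
segmentation thresholds; the pipeline is built so that its contact
readouts are functions of the *physical* scene, not of how it was
photographed.

## À trous wavelet detection

The undecimated B3-spline wavelet ("à trous") transform smooths the
raster repeatedly with the separable kernel [1, 4, 6, 4, 1]/16 whose taps
are spread 2^(j−1) pixels apart at scale j (zeros "with holes" in
between); wavelet plane w_j is the difference of successive smooths, and
the planes plus the final smooth residual reconstruct the input exactly.
Because nothing is decimated, significance decisions are available at
every pixel of the original raster.

Borders are extended by mirror reflection (no edge repeat), which avoids
spurious edge coefficients next to tissue borders. Coordinates are
row-major, 0-based, pixel-centered.

**Noise calibration.** The per-scale noise σ_j can be estimated two ways:

- *propagate* (default API): σ_1 = MAD(w_1)/0.6745, then σ_j = σ_1 · f_j
  with fixed factors f_j measured once from 50 seeded 512×512
  unit-variance white-noise rasters (f = 1, 0.2253, 0.0963, 0.0466,
  0.0233, 0.0117; the absolute scale-1 level of unit white noise is
  0.8908). This is cheap and standard but assumes white noise.
- *per-scale* (used by the pipeline): MAD of each plane individually.
  Resampled images have spatially correlated noise, for which white-noise
  propagation underestimates coarse-scale σ by large factors (we measured
  ≈13 spurious zones per channel at 2× upsampling with propagation, zero
  with per-scale MAD). Per-scale MAD assumes structures are sparse enough
  that each plane's median is noise-dominated, which holds for the
  sparse-cell regime this pipeline targets (object coverage ≲ 25%).

A coefficient is significant when |w_j| > k·σ_j; k = 3 by default (the
two-sided Gaussian 3σ tail flags ≈0.27% of pure-noise coefficients at
scale 1, which the tests check against a [0.1%, 0.6%] band that allows
for coefficient correlation). Zone construction keeps only positive
coefficients: IF signal is bright on dark.

## From coefficients to zones

Zones are 8-connected components of the union of positive significant
masks over a chosen scale set. Two refinements matter in practice:

- **Physical scale selection.** Scale j responds to structure about
  2^j pixels ≈ 2^j · pixel_size µm across. The pipeline selects the
  scales whose equivalent width falls in [1.5, 6) µm — bracketing
  lymphocyte-sized cells (7–9 µm diameter) — so the same physical
  structures are selected at any sampling density. A fixed scale set is
  available through `scales_used` in the configuration.
- **Half-maximum trimming.** A threshold in the noise floor places the
  zone boundary where the PSF tail still clears k·σ, dilating every zone
  by roughly the PSF width (~30% area bias at our settings, and a ~3×
  bias on thin overlap areas). The 50% contour of a blurred step edge
  sits on the true boundary, so each component is trimmed to
  background + 0.5·(plateau − background), computed on a lightly
  smoothed raster with the plateau taken as the median of the brighter
  half of the component. This removes the bias (zone areas within a few
  % of planted truth) at the cost of assuming roughly plateau-like
  objects. `refine="none"` gives the raw significance support.

Components smaller than `min_area_um2` (default 20 µm², about half a
lymphocyte cross-section) are discarded.

## Contact readouts

With zone supports Z_A and Z_B:

- overlay area = |Z_A ∩ Z_B| (µm²); Manders-style per-channel fractions
  |Z_A∩Z_B|/|Z_A| and /|Z_B| are reported for transparency.
- overlay integrated intensity = Σ over the intersection of
  min(I_A, I_B), multiplied by the pixel area, so its value is in
  intensity·µm² and does not change with sampling density.
- contact score = overlay intensity / (|Z_A| + |Z_B|): dual-positive
  signal per µm² of significant zone. Dividing by the summed zone areas
  normalizes away section-to-section differences in how much of either
  population is present.
- object-level contacts: zones are paired when their boundary gap is at
  most `max_gap_um` (default 1 µm ≈ membrane apposition at ×400). The
  gap between two zones is max(0, d − √2 px)·pixel_size where d is the
  nearest center-to-center pixel distance, so pixel overlap and
  8-adjacency count as gap 0 exactly; the definition undershoots a
  geometric boundary gap by ≲ 0.4 px, which is below any threshold used.
  All qualifying pairs are reported (no one-to-one matching), and
  `contact_fraction_B` is the fraction of B zones touched by ≥ 1 A zone.

## Zoom independence

Expressing thresholds in micrometres is necessary but not sufficient: an
image acquired at lower magnification carries more blur per micrometre
(optics + sampling), which moves any intensity-threshold boundary and
especially distorts the thin (~1–2 µm) contact lenses between apposed
cells. The pipeline therefore standardizes each image before analysis:

1. resample to a 0.25 µm/px working grid (bilinear);
2. add Gaussian blur so the total effective resolution is σ = 1.0 µm,
   with native blur modeled as sqrt(psf² + (0.45·native_px)²).

After standardization the processing chain is identical for any
acquisition zoom. On 20 seeded scenes resampled by factors 0.5–2.0 the
contact score deviates at most 3.9% from its native-resolution value and
the contact fraction deviates 0 — within the 5% band the tests enforce.
The residual score deviation comes from information genuinely absent at
the coarsest sampling. Standardization can be disabled
(`standardize: false`), in which case only physical-unit thresholds
protect against zoom changes.

## Field metrics

`area_fraction` is the zone-support area over the tissue area (whole
raster when no tissue mask is given). Cell counting mimics the
pathologist's protocol: square high-power fields (350 µm default for real
×400 sections; 40 µm in the synthetic study, whose field of view is
128 µm) are placed without overlap, either seeded-randomly or on a grid,
and each zone is counted in the single field containing its centroid
(half-open field squares make the partition exact).

## Group statistics and lysis

Kruskal–Wallis uses midranks with the standard tie correction; the
asymptotic p is the χ² tail with g−1 degrees of freedom. The Monte-Carlo
p permutes group labels (ranks are invariant, so permuted statistics are
recomputed from re-sliced rank sums, vectorized); the add-one estimator
(b+1)/(B+1) cannot return 0, and the binomial standard error of p_MC is
reported. Both p-values are always computed; a flag marks tables with any
group below n = 5, where the asymptotic χ² approximation is doubtful.
Calibration checks: exact agreement of H with the hand-evaluated
three-triple example (H = 7.2), p_MC within 3 SE of the exhaustive
1680-assignment permutation p, type-I error within [0.035, 0.065] at
α = 0.05 over 1,000 null tables, and ≥ 70% power at a 1.5-SD location
shift with n = 8 per group.

Specific lysis is `%CFSE-high × 100 / %CFSE-low`, exactly as the assay
defines it. Note the orientation: 100 means no antigen-specific killing
and 0 complete elimination of the pulsed (CFSE-high) targets — inverted
relative to the common "% specific lysis" convention; the value is
reported as printed, without re-orientation.

## Synthetic study conditions

The generator emulates a sparse ×400 IF field, 128×128 µm at 0.5 µm/px
(zoom factor 1):

- 12 cells per population by default, disk-shaped with radius
  3.5 ± 0.3 µm (CD8 T cells and leukemic blasts are ~7–9 µm across;
  disks preserve exact area/contact ground truth);
- a set fraction of B cells placed in membrane apposition to an A cell
  (1 µm center-line overlap), the rest ≥ 5 µm clear of every A cell;
  same-channel cells keep ≥ 3 µm separation so objects stay resolvable;
- rendering: Gaussian PSF σ = 0.5 µm, background 10, peak 150, Poisson
  shot noise plus Gaussian read noise (SD 5) — SNR ≈ 24 by the
  (peak − background)/background-noise-SD definition, comfortably inside
  the SNR ≥ 5 regime the validation targets;
- zoom is modeled as sampling density: the physical scene is fixed and
  rasterized at pixel_size/zoom.

What the generator does *not* emulate: tissue texture and
autofluorescence, irregular cell shapes, intensity gradients, optical
aberrations, and the DAB/brightfield character of the IHC counts (IF-like
rasters stand in). Passing tests therefore demonstrate correctness of the
measurement chain under controlled conditions, not robustness to every
property of real tissue.

Group tables are Gaussian per animal; CFSE events are two log-normal dye
populations (10× dose separation, σ_log = 0.3) mixed 50:50, with a set
fraction of the high population removed before recovery.

## Numerical and reproducibility choices

- All generators and the Monte-Carlo test are pure functions of
  (parameters, seed); permutation p-values are bitwise reproducible.
- CSV output uses 6 significant digits for byte-stable reruns; every
  output directory receives the fully-resolved configuration.
- Degenerate inputs: constant rasters produce zero planes, zero sigmas
  and empty masks (H = 0, p = 1 for all-tied tables); empty zone maps
  yield zero scores rather than errors; infeasible packings raise errors
  naming the feasible maximum.
- The decomposition requires the dilated kernel to fit
  (2^(J−1)·4 < min(image dimension)); noise propagation factors are
  shipped for scales 1–6, which covers images up to ~4k pixels on the
  working grid.

## Known limitations

- Half-max refinement assumes plateau-like objects; faint or strongly
  graded structures will be under-segmented relative to eye.
- Per-scale MAD noise estimation biases σ upward (and detection slightly
  conservative) when bright structure covers a large share of the frame.
- Contact pairing reports adjacency, not biological synapse formation;
  at very high density the 1 µm gap rule will pair cells that merely
  crowd each other.
- The equivalence of "immunoreactive cells" with wavelet-detected zones
  operationalizes a count a pathologist does by eye on DAB sections;
  absolute counts on real IHC may differ even where relative comparisons
  are sound.
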