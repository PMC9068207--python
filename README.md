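# trapscope

Quantification of cell–cell contact between two immunofluorescence (IF)
channels — e.g. CD8⁺ effector T cells and NPMc⁺ leukemic cells in bone-marrow
sections — together with the companion tissue readouts (marker-positive area
fraction, immunoreactive-cell counts over nonoverlapping high-power fields),
Monte-Carlo Kruskal–Wallis group statistics and the CFSE in-vivo
cytotoxicity (specific lysis) readout.

## Who this is for

Groups that image two stained cell populations and need a reproducible,
magnification-independent number for "how much do these populations touch",
plus the routine per-animal statistics that go with it. Everything is
validated end-to-end on seeded synthetic micrographs with known ground
truth, so no external data are needed to test or demonstrate the pipeline.

## The method

**À trous wavelet detection.** Each channel raster I is decomposed with the
undecimated ("with holes") B3-spline wavelet transform: smoothing with the
separable kernel [1, 4, 6, 4, 1]/16, dilated by 2^(j−1) at scale j, yields
c_0 = I, c_1, …, c_J and detail planes w_j = c_{j−1} − c_j with

    I = w_1 + … + w_J + c_J        (exact, at full image resolution)

A coefficient is *significant* at scale j when |w_j| > k·σ_j (default
k = 3), where σ_j is the noise standard deviation of plane j estimated
robustly (MAD/0.6745). Significant zones are 8-connected components of
positive significant coefficients over the scales whose physical width
matches cell-sized structure, trimmed to their half-maximum intensity
contour and filtered by a minimum physical area.

**Contact readouts.** For channels A and B with zone supports Z_A, Z_B:

    overlay area      = |Z_A ∩ Z_B|                          (µm²)
    overlay intensity = Σ_{x ∈ Z_A∩Z_B} min(I_A, I_B) · a_px (intensity·µm²)
    contact score     = overlay intensity / (|Z_A| + |Z_B|)

i.e. the dual-positive (yellow) signal measured only within the significant
zones and related to their own areas. Object-level contact counts pair
every A-zone and B-zone whose boundary gap is ≤ 1 µm (gap 0 = overlap or
8-adjacency), and `contact_fraction_B` is the fraction of B cells touched
by at least one A cell. All thresholds are in micrometres, and images are
first standardized to a common working grid (0.25 µm/px) and analysis
resolution (Gaussian σ = 1 µm), which together make the readouts
independent of the acquisition zoom factor.

**Group statistics.** Tie-corrected Kruskal–Wallis H with the χ² p-value
and a Monte-Carlo permutation p, p_MC = (b+1)/(B+1) over B random label
permutations. **Specific lysis** is computed exactly as printed on the
CFSE readout: `%CFSE-high × 100 / %CFSE-low` (100 = no specific killing,
0 = complete elimination of peptide-pulsed targets).

## Worked example

Generate three synthetic two-channel scenes (12 CD8⁺ and 12 NPMc⁺ cells,
half the NPMc⁺ cells planted in contact) and quantify them:

```bash
trapscope simulate scene --out demo --seed 5 --n 3 --contact-fraction 0.5
trapscope quantify demo/*.tiff --channel CD8 --channel NPM \
    --pixel-size-um 0.5 --out demo_out
```

`demo_out/quantification.csv` (selected columns):

```
     image  overlay_area_um2  contact_score  n_objects_A  n_objects_B  n_contacting_pairs  contact_fraction_B
scene_0005           13.0625        1.27517           12           12                   6                 0.5
scene_0006           13.4375        1.23238           12           12                   6                 0.5
scene_0007           13.7500        1.41542           12           12                   6                 0.5
```

All 24 planted cells are found in each scene, the 6 planted touching pairs
are recovered exactly (`contact_fraction_B` = 0.5 = ground truth), and the
contact score is the overlay intensity per µm² of significant zone.

Group comparison on a per-animal table (three groups of 8, one group
shifted low):

```bash
trapscope simulate groups --out demo --seed 5
trapscope stats demo/groups.csv --permutations 10000 --seed 1
```

```json
{"H": 15.485, "df": 2, "p_asymptotic": 0.000434, "p_mc": 0.00020,
 "mc_se": 0.000141, "n_permutations": 10000, "significant": true}
```

The lysis readout: `trapscope lysis --pct-hi 3.2 --pct-low 8.1` prints
`39.5062` (39.5% of the no-killing reference ratio, i.e. strong
antigen-specific killing).

## Layout

- `src/trapscope/wavelet.py` — à trous transform, noise estimation,
  significance masks
- `src/trapscope/zones.py` — zone segmentation, overlay/contact scoring
- `src/trapscope/fields.py` — area fractions, high-power-field counts
- `src/trapscope/stats.py` — Kruskal–Wallis (+ Monte Carlo), specific lysis
- `src/trapscope/synth.py` — seeded synthetic scenes, group tables, CFSE
  events with ground truth
- `src/trapscope/pipeline.py`, `config.py`, `cli.py` — orchestration,
  configuration and the `trapscope` command

See `docs/methods.md` for the modeling choices, parameter defaults and
known limitations.
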