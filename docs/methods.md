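# Methods

This document records the model behind `tolfish`, the parameter defaults and
why they were chosen, and the numerical design decisions that matter for
reproducing or extending the analysis.

## 1. Regulatory logic (`tolfish.logic`)

Expression of the two TOL operon reporters is modeled as a discrete truth
table over `(genotype, inducer, iptg, rifampin)` — 96 conditions in total.

* **Pu (xylUW, upper pathway).** Driven by XylR bound to an *upper-pathway
  effector* (m-xylene, toluene, o-xylene). Benzoate and 3-methylbenzoate are
  not XylR effectors, so Pu stays OFF under them.
* **Pm (xylX, meta pathway).** Driven by XylS, which is activated either
  directly by benzoate/3-methylbenzoate or by XylS overexpression downstream
  of an active Pu (the regulatory cascade). Hence any upper-effector
  condition that fires Pu also fires Pm in the wild type.
* **PU→T7 variants.** In the engineered strains, *xylUW* is transcribed by
  phage T7 RNA polymerase under IPTG control. Without IPTG the T7 system is
  leaky: `xylUW = LOW`. In the host that lacks T7 polymerase, the construct
  is inert for *xylUW* but Pu-driven XylS overexpression still fires Pm.
* **Rifampin.** Blocks host RNA polymerase only. All host-RNAP transcripts
  (always *xylX*, and *xylUW* except in the T7-polymerase host) go OFF, and
  the spatial phenotype flag `focal` becomes `False`: transcripts made by the
  rifampin-resistant T7 polymerase no longer condense into foci but fill the
  cytoplasm.

Levels are ordered `OFF < LOW < HIGH` so monotonicity properties (e.g.
rifampin never increases expression) are testable.

## 2. Synthetic micrograph generator (`tolfish.simulate`)

### Geometry

Cells are 2-D spherocylinders (capsules) with random pose, length uniform in
2.0–4.0 µm and width in 0.8–1.0 µm at 0.065 µm/px (≈ 31–62 × 12–15 px),
placed without overlap on a 512×512 field (`RuntimeError` after 1000 failed
placements, so overly dense configurations fail loudly rather than silently
clumping). The nucleoid is a 1- or 2-lobe anisotropic Gaussian density
spanning ~60% of the cell length.

### Zones and focus placement

Each cell's noiseless nucleoid density, min–max normalized over the cell,
defines three zones by thresholds **0.5** (dense) and **0.2** (diffuse):
`DENSE` (≥0.5), `PERIPHERAL` ([0.2, 0.5)), `FREE` (<0.2). mRNA focus zones
are drawn from the categorical weights `zone_weights = (0.01, 0.15, 0.84)` —
the strongly nucleoid-excluded distribution the package is built to measure.

**Placement invariant:** the zone category is drawn *once*; placement
constraints (membrane margin ≥2 px, same-channel separation ≥5 px,
independence distance ≥9 px from plasmid foci) only resample the *position*
within the chosen zone. Redrawing the zone on a constraint violation would
re-weight the realized mixture toward zones with more room (the FREE polar
caps are small in pixel area) and bias the ground truth away from
`zone_weights`.

Plasmid (green) foci: 1–2 per cell (P(1) = 0.7, P(2) = 0.3, mean 1.3).
mRNA (red) counts are Poisson(1.4) per
cell when the condition is expressing. The pairing mix
`(COLOCALIZED, ADJACENT, SEPARATE) = (0.3, 0.5, 0.2)` assigns each red focus
a relationship to an available plasmid focus (each plasmid anchors at most
one paired mRNA, so one-to-one matching is recoverable); colocalized ≤2 px,
adjacent 2–8 px, separate/independent ≥9 px.

### Photometry and noise

Foci are Gaussian PSF spots, σ = 1.3 px. Defaults: `mrna_amplitude` 600,
`plasmid_amplitude` 500 over `background` 200 counts, `dapi_peak` 4000,
Poisson shot noise plus Gaussian read noise (`read_sigma` 10), clipped to
uint16. Peak SNR ≈ 20: detection is reliable but not trivial (empty cells
stretched by per-cell normalization must not produce false positives). In
rifampin conditions the per-cell mRNA photon budget is spread uniformly over
the cytoplasm instead of rendered as spots.

Setting `read_sigma = 0` and `photon_scale = inf` gives a noiseless limit in
which the analysis pipeline must agree with the generator truth exactly; the
test suite uses this to separate model error from noise error.

### Scope and limits

The generator is 2-D (a single focal plane), has no camera PSF beyond the
spot Gaussian, no photobleaching, no cell-to-cell expression variability
beyond Poisson counts, and no z-dependent defocus. It is a calibration
target for the analysis code, not a physical microscope model.

## 3. Segmentation and contours (`tolfish.segment`)

* **Segmentation.** Otsu threshold on the smoothed phase image (cells dark),
  hole filling, then a distance-transform watershed. Seeds are *distance
  cores*: per connected component, pixels with distance above
  `core_fraction = 0.7` of that component's maximum. A single rod's medial
  ridge is a plateau — point local maxima would over-split straight cells —
  while two rods joined end-to-end by a neck thinner than 70% of the ridge
  get two disconnected cores and are separated. Parallel rods that overlap
  laterally have no neck at all and are geometrically inseparable in 2-D;
  such fields should be avoided or masked.
* **Normalization.** Per-cell min–max to [0, 1]; pixels outside the cell are
  NaN; a flat channel normalizes to zeros with a warning.
* **Contours.** Marching squares with linear interpolation between pixel
  centers. Before contouring, outside-cell/NaN pixels are filled with the
  sentinel −0.1 (below any level in (0,1)) and the raster is padded by one
  sentinel pixel, so every contour closes — along the mask edge when clipped
  by the cell, along the image border otherwise. Without a cell mask, a
  raster whose finite values never cross the level returns `[]` (the padding
  must not manufacture a ring around a constant image). Contours enclosing
  < 2 px² are discarded as noise.
* **Nucleoid zones.** Dual levels 0.5 (dense) and 0.2 (diffuse) on the
  normalized DAPI channel. Because both level sets come from one function,
  dense polygons must nest inside the diffuse union; a violation beyond a
  0.25 px buffer and 5% area tolerance raises — it indicates a contouring
  bug, not data.

Verified accuracy: polygon area matches 10× supersampled (bilinear) pixel
counting within 2% on random smooth fields; a sampled Gaussian's iso-circle
is recovered with < 0.25 px mean radial deviation; a binary disc's area is
within 5% of πr².

## 4. Spot detection and dispersion (`tolfish.spots`)

Scale-normalized Laplacian-of-Gaussian over σ ∈ [1.0, 2.5] (5 scales) on the
per-cell normalized channel (outside-mask pixels median-filled first so the
LoG sees no mask edge). Candidates must exceed both an absolute floor
(`threshold = 0.10`) and an adaptive robust threshold: median + 6.5·MAD of
the in-cell response (the MAD term is what keeps normalized empty cells
quiet). Non-maximum suppression at 3 px. Centroids are refined by iterative
background-subtracted center-of-mass in a ±2 px window; measured RMSE
~0.06 px on the default preset, with recall and precision > 0.99.

**Dispersion index.** Fraction of background-subtracted in-cell signal inside
4 px discs around detected foci; ≥ 0.5 → FOCAL, else DISPERSED. A presence
gate runs first on the *raw* channel: the mean in-cell elevation above the
field background (median/MAD of cell-free pixels) must exceed 4 standard
errors, otherwise NO_SIGNAL. Cells with zero generated foci are genuinely
signal-free — Poisson(1.4) leaves ~25% of expressing cells empty — so
NO_SIGNAL for them is correct, not a detection failure.

## 5. Colocalization (`tolfish.coloc`)

* Zone classification is exact point-in-polygon (even–odd) against the
  nucleoid contours, validated against an independent ray-casting oracle on
  1000 random points.
* `region_overlap` computes polygon-intersection areas with shapely
  (fraction-of-A and Jaccard; NaN on zero denominators), validated against
  10× supersampling within 2%.
* Pairing is greedy nearest-first one-to-one matching with bands
  `d_coloc = 2` px, `d_adj = 8` px.
* `line_profile` samples a channel along a segment by bilinear
  interpolation, averaged across a perpendicular width.

## 6. Reporting (`tolfish.report`, `tolfish.pipeline`)

Summary statistics (foci per cell, zone fractions, pairing fractions,
dispersed-cell fraction) with 95% percentile bootstrap CIs resampling *cells*
(not foci) with replacement, 1000 replicates, seeded. Cell ids are sorted
before resampling so results are invariant to input row order. The
denominator for per-cell rates is configurable (`all_cells` vs
`cells_with_foci`). `compare_conditions` bootstraps the difference between
two groups from their per-cell count vectors.

`run_pipeline` chains simulate → segment → detect → classify → summarize and
writes `foci.csv`, `cells.csv`, `dispersion.csv`, `summary.csv` and a
`manifest.json` recording the resolved config and seed; identical configs
produce byte-identical outputs. Config schemas are validated eagerly —
unknown sections or keys raise before any computation.

Probe manifests (CSV/TSV with `probe_id`, `sequence`, …) are validated
character-by-character (ACGTU, case-insensitive) with row-indexed error
messages; probe length is derived from the sequence.

## 7. Determinism

Every stochastic step derives its generator from
`np.random.SeedSequence(seed).spawn(...)`, one child per field and per cell,
so adding fields or reordering analysis does not perturb earlier draws. The
acceptance script (`scripts/acceptance.py`) and the pipeline are end-to-end
reproducible from a single integer seed.

## 8. Known limitations

* 2-D only; no axial information, so zone fractions are projections.
* The watershed cannot split laterally overlapping parallel rods (no neck).
* The dispersion presence gate needs cell-free background pixels in the
  field; fully confluent fields would need an explicit background estimate.
* Pairing recovery assumes the generator's one-paired-mRNA-per-plasmid
  convention; biological multi-mRNA bursts at one locus would require a
  many-to-one matcher.
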