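# Methods

This note documents the models, parameter choices and numerical decisions
behind `spotscreen`, and what the synthetic validation does and does not
establish about real screening data.

## The analysis model

One *field* is a multi-channel 16-bit image of a single camera position:
an array spot (one image per spot), or one of several subpositions within
a plate well (9 for 384-well, 25 for 96-well plates). The pipeline maps
each field to per-nucleus measurements and pools them into per-position
(spot or well) readouts:

1. **Background subtraction.** The nuclei channel is opened with a
   *ball-top* (hemispherical, non-flat) structuring element of radius 50
   px and the opening is subtracted — the classical rolling-ball
   background estimate, computed exactly rather than with the paraboloid
   approximation. Arithmetic is float32; outside the image the signal is
   treated as ±∞ (border pixels therefore see a truncated ball). The
   operation is anti-extensive and, up to the ball-top discretization
   residue (≤ 1 count on smooth images, a few counts at the noise scale),
   idempotent.
2. **Binarization.** Foreground = (value ≥ Otsu global threshold) AND
   (value > moving mean over a 51-px window + offset 0). The global
   threshold maximizes between-class variance on a 256-bin histogram and
   is returned as the lower edge of the first foreground bin, so
   classification by `>=` reproduces the optimal histogram cut exactly.
   Otsu's threshold is meaningless on object-free (unimodal) images, so
   the global step additionally requires a minimum separation
   effectiveness η = σ²(between)/σ²(total) of 0.75; measured values are
   ~0.64 for pure noise and ≥ 0.85 once a field contains even a handful
   of nuclei. Below the cutoff the field is declared empty.
3. **Cleanup and labelling.** Hole filling, binary opening with a disk of
   radius 2 px, removal of components below 40 px, 8-connected component
   labelling; components touching the field border are excluded by
   default (`exclude_border`). The original workflow states none of these
   values; all are exposed in `SegmentationParams`. There is no watershed
   splitting — touching nuclei merge, a documented limitation (the
   generator's default placement keeps footprints non-adjacent).
4. **Features.** `num_pix` (area), `extend` (area / bounding-box area),
   perimeter, circularity 4πA/P², eccentricity, intensity mean/sd/entropy
   and the 0-based centroid, measured on the background-subtracted image.
   The perimeter is the *crack-edge* count (number of 4-neighbour
   foreground/background pixel edges): a digital n×n square then has
   P = 4n and circularity ≈ 0.785, at the cost of a low circularity
   (≈ 0.6) for digital disks — acceptable because circularity is used
   comparatively, not as an absolute roundness measure.
5. **Phenotype classification.** Gaussian class-conditional model
   (quadratic discriminant) over (`num_pix`, `extend`, `circularity`,
   `mean_intensity`), fitted on standardized features with
   maximum-likelihood covariances regularized by 1e-6·trace/d on the
   diagonal. Maximum-likelihood (rather than unbiased) covariances make
   the fit invariant under dataset replication. Posterior ties break in
   the order normal < spindle < cytokinesis. Texture features are
   excluded by default because the generator's texture model is
   simplistic. A transparent rule-based classifier (thresholds on area,
   extent, circularity) ships as an auditable fallback. Training data
   come from class-pure generated fields segmented by the same chain, so
   the classifier learns the *measured* feature distributions, including
   segmentation bias.
6. **Spot ROI.** On arrays the Cy3-labelled transfection spot is detected
   by Otsu thresholding of the marker channel (largest component,
   centroid + equivalent-circle radius), guarded by the same η ≥ 0.75
   rule and a 1–90% foreground-fraction window; otherwise a centered
   fallback disk with the nominal printed-spot radius (300 µm diameter)
   is used. Nuclei whose centroid falls outside the disk are discarded.
   Well images carry no marker and use the whole field.
7. **EGF readout.** Each nucleus is dilated by the ring width (default
   5 px ≈ 5 µm at the default sampling) in the chessboard metric; rings
   exclude all nucleus footprints, and contested pixels go to the nucleus
   with the nearer centroid, so rings partition the perinuclear zone
   without double counting. The per-cell readout is the plain mean cargo
   intensity in the ring (granules included — no spot detection); the
   field readout is the unweighted mean over cells; position readouts are
   cell-weighted. The ring width is the single most result-sensitive free
   parameter of this readout and is carried in every report.
8. **Aggregation.** Per-position fractions are total class counts over
   total cells (cell-weighted pooling, identical to recomputation from
   concatenated per-cell labels and invariant to subposition order).
   EGF normalization defaults to percent-of-negative-control per
   replicate; raw means are always retained, since the natural baseline
   of a percent scale is not uniquely defined.

## Statistics

All tests operate on position-level readouts (one value per spot or
well): this is the unit at which spot-to-spot and well-to-well
variability is comparable across platforms, and the granularity at which
post-hoc p-values of realistic magnitude arise.

* **Welch one-way ANOVA** (k ≥ 2 groups, unequal variances): with
  w_i = n_i/s_i², F = [Σ w_i(x̄_i−x̄_w)²/(k−1)] / [1 + 2(k−2)/(k²−1)·Λ],
  Λ = Σ(1−w_i/Σw)²/(n_i−1), df = (k−1, (k²−1)/(3Λ)). Note the
  denominator correction: for k > 2 Welch's F equals the classical
  one-way F only asymptotically, even under homoscedastic balanced
  designs; at k = 2 (where the correction vanishes) it equals the squared
  Welch t exactly.
* **Games–Howell** post-hoc: per pair, SE = √(s_i²/n_i + s_j²/n_j),
  Welch–Satterthwaite df, q = √2·|x̄_i−x̄_j|/SE, adjusted
  p = 1 − F_Q(q; k, df) from the studentized-range distribution with k =
  number of groups. The family adjustment is inherent; no further
  correction is applied.
* **Studentized-range CDF**: own implementation as the scale mixture
  P(Q ≤ q) = ∫ f_ν(s)·P(range of k normals ≤ qs) ds with the χ_ν/√ν
  scale density, evaluated by composite Gauss–Legendre panels (24 nodes,
  inner z-range [−9, 9], outer s-range from χ² quantiles at 1e-14) with
  panel doubling until successive refinements agree to 1e-8. Agreement
  with an independent reference implementation is ~1e-13 across
  k ∈ [2, 10], ν ∈ [3, 120]; a call costs ~2 ms.
* **Variance layer**: Bartlett's χ² test (computed from group summaries),
  a two-sided variance-ratio F test (p = 2·min(tail, 1−tail)), and the
  intra-plate variance (variance over positions within a replicate,
  averaged over replicates).
* **Replicate equivalence**: n_a = (Var_a/Var_w)·n_w follows from
  SE = √(Var/n); the exact value and its ceiling are both reported.
* **Replicate correlation**: Pearson r of position-level readouts paired
  by (condition, position) across replicates; with three replicates the
  mean of the three pairwise r values.

## The synthetic generator

The generator emulates the study conditions the pipeline is meant for —
it is a fixed experimental stand-in, not a tuning dial:

* **Scale.** Default 1.0 µm/px (typical for binned 20× high-content
  acquisition) on 384×384 fields, so the 300 µm printed spot (radius
  150 px) fits with margin. Pixel size is a free configuration parameter;
  nothing in the geometry is tied to it.
* **Counts.** Poisson cell numbers; defaults of ~156 cells per array spot
  for the cell-cycle assay, ~93 for the EGF assay, and ~178 per 384-well
  subposition (1600 cells/well over 9 subpositions).
* **Nuclei.** Normal: ellipses with semi-axes ~7.5/5.5 µm (≈130 µm², a
  typical interphase HeLa nucleus; at the array density of 156 cells per
  300 µm spot this yields ≈29% nuclear area coverage, the highest the
  non-touching placement can sustain — markedly larger nuclei would make
  the published density geometrically unreachable without touching).
  Spindle: near-circular, 60% of normal area, 1.8× chromatin intensity
  (condensation). Cytokinesis: 2–4 overlapping lobes forming one
  connected footprint at 1.5–2× normal area, with lobe areas inflated
  25% to offset the union overlap. Per-cell lognormal-like gain (15% CV)
  and smooth multiplicative texture (8%).
* **Placement.** Reject-and-resample: a candidate footprint is accepted
  only if its 1-px dilation avoids all previous footprints, so distinct
  nuclei are never 8-adjacent; with a marker spot, centroids are drawn
  uniformly in the disk. Cells that cannot be placed within 3000
  attempts are dropped and counted (rare, <1% at default densities).
  `allow_touching` disables the constraint for stress tests.
* **Cargo.** Per-cell true ring intensity ~ N(2000, 600²) counts (≈30%
  cell-to-cell CV of EGF uptake), painted additively on a 7-px chessboard
  annulus, plus Poisson(4) punctate granules (amplitude 2500, σ 1.2 px)
  inside the annulus; knock-down scales every EGF-specific intensity by
  the condition's factor while the additive background (60 counts) stays.
  The measured 5-px ring always lies inside the painted 7-px annulus.
* **Noise.** Background plane (100 counts + small linear gradient) →
  objects → Poisson shot noise → Gaussian read noise (σ 40) → clip to
  [0, 65535] → round to uint16. Rendering is integer-quantized and
  bit-identical for a fixed seed; per-field seeds derive from the master
  seed and a CRC of (replicate, position, subposition), so any single
  field can be regenerated independently.

**What passing the synthetic recovery shows — and what it does not.**
The generator has no optics (no PSF, no defocus), no cytoplasmic
autofluorescence, no mitotic-figure texture, no cell debris, and its
default placement forbids touching nuclei. Recovery of phenotype
fractions to ±5 points and densities to ±10% therefore validates the
*pipeline logic* — thresholding, labelling, feature computation,
classification, ring partitioning, pooling and statistics — not
robustness to the hardest aspects of real images (touching/overlapping
nuclei, staining artifacts). On real data the missing watershed split is
the first limitation one would hit at confluence; the EGF readout is
additionally biased low by a few points because neighbouring cells' EGF
halos genuinely add (measured per-cell fidelity is r ≈ 0.97 for isolated
cells and degrades with crowding), and because the additive background
does not scale with knock-down (≈2 points at default settings).

## Numerical and design choices

* Global AND local threshold combination: AND suppresses the local
  method's background speckle and the global method's dim halos.
* Coordinates are 0-based (row, col); bounding boxes half-open; label
  maps always the contiguous set 1..K in ascending original order.
* Ring dilation uses the chessboard metric (a width-1 ring around a
  single pixel is its 8-neighbourhood); ring ownership ties break toward
  the lower label.
* `measure_cargo` reports every label, with ring_px = 0 and a NaN mean
  for degenerate (empty-ring) cells, which callers exclude and count.
* Degenerate inputs raise: constant images for Otsu, even local windows,
  balls larger than the image, zero-variance groups in every variance
  test, missing conditions and malformed layout rows (with the row
  number).
* Classifier training defaults: 3 class-pure fields of ~70 cells per
  class (≈600 nuclei), enough for stable 4-feature Gaussian fits while
  keeping a full training run under ~5 s.
* Problem sizes in the test suite and acceptance script (27-field
  screens, 2000-replication calibration at k = 4, n = 10, a 10⁶-draw
  Monte-Carlo check of the range distribution) were chosen as the
  smallest sizes at which the targeted tolerances are statistically
  meaningful.

## Known limitations

* No splitting of touching nuclei (no watershed); crowded real images
  will undercount.
* The EGF percent scale needs an explicit baseline choice; both
  normalized and raw means are reported.
* The studentized-range integration assumes ν ≥ 1; fractional ν below 1
  is rejected rather than handled.
* Rule-based classifier thresholds are expressed in pixels at the default
  sampling and must be rescaled for other pixel sizes.
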