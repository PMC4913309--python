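# Methods

This note records the models, algorithms, parameter choices and numerical
conventions behind `qdcount`, and what the synthetic-data validation does
and does not establish about real microscopy data.

## Coordinate and data conventions

Pixel indices are 0-based; (x, y) = (column, row); sub-pixel positions are
continuous with pixel centers at integer coordinates. Stacks are indexed
(z, y, x). Outline polygons rasterize by the pixel-center rule (a pixel
belongs to a cell iff its center is inside or on the boundary; overlapping
polygons resolve to the lowest cell id). Calibration units are nanometers
for pixel size and slice spacing; intensities are camera counts (ADU).

## Synthetic scene model

The generator emulates one field of view of a fixed-cell, antibody–quantum
dot labeling experiment imaged as a z-stack:

- **Geometry.** Defaults: 1024×1024 pixels at 160 nm, 60 slices at 300 nm
  (18 µm depth) — a high-magnification, high-NA configuration. Cells are
  non-overlapping disks of radius 40–55 px (13–18 µm diameter, suspension
  leukemia-cell scale), rejection-sampled with a 6 px clearance margin;
  placement failure raises an explicit error rather than silently crowding.
- **Counts.** Per-cell ground-truth emitter counts are negative binomial
  (default mean 100, dispersion 5, i.e. CV ≈ 0.46, matching the broad
  per-cell heterogeneity seen in single-cell phospho-measurements).
  Overdispersed counts are the norm for per-cell molecule numbers; the
  downstream scoring is distribution-free, so the NB family is a
  representative choice, not a commitment. Explicit per-cell counts can be
  forced for targeted tests.
- **Emitters.** One emitter = one tagged complex, placed uniformly in the
  cell disk at a uniform continuous z, rendered as a separable 3D Gaussian
  (σ_xy = 1.1 px ≈ 176 nm; σ_z = 1 slice ≈ 300 nm). Blinking is not
  simulated: counting operates on z-linked detections, so intermittency
  would only matter through slice-gap tolerance, which is exercised
  directly. An optional minimum-separation mode supports clean
  localization tests; the default is uniform (collisions allowed).
- **Autofluorescence.** Per cell, a smooth random texture (Gaussian scale
  12 px ≈ 2 µm, organelle-scale haze; 20% relative SD) multiplied by the
  projected-chord profile of a sphere, √(1 − (d/r)²), and blurred at the
  PSF scale. The chord taper is the physically correct column density of
  fluorophores filling a round cell; it also matters numerically — a
  hard-edged disk of ~50 counts rings in the detection band-pass and
  produces spurious rim maxima comparable to true spots.
- **Camera.** Expected photons → Poisson; + Gaussian read noise (SD 4);
  + constant baseline offset (100); rounded and clipped to the 16-bit
  range. Defaults give an in-cell peak S/N of
  80 / √(50 + 4²) ≈ 10 for a single emitter.
- **Reproducibility.** One master seed; per-cell substreams spawned from
  it, so increasing `n_cells` leaves earlier cells bit-identical; the
  camera noise stream is separate. Identical specs give bit-identical
  stacks and tables.

What the generator does *not* emulate: real PSF aberrations and axial
asymmetry, QD blinking and spectral crosstalk, labeling stoichiometry
(binding is 1:1 by construction), cell-shape irregularity, z-dependent
haze, and stage drift. Passing the suite therefore demonstrates the
algorithms are correct and well-calibrated under the stated imaging model,
not that the defaults transfer untouched to any particular microscope.

## Population model

Untreated per-cell counts: NB(µ₀, θ). Treated: with probability
`insensitive_fraction` a cell keeps the untreated distribution, otherwise
its mean is µ₀(1 − inhibition) at the same θ. Defaults (µ₀ = 100, θ = 5,
inhibition 0.8, insensitive fraction 0.2, 200 cells per condition) emulate
a potent kinase inhibitor leaving a resistant subpopulation, at realistic
sampled-cell numbers. Setting inhibition = 0 or insensitive fraction = 1
collapses the mixture to the untreated distribution exactly (same draws
under the same seed).

## Detection chain

- **Band-pass.** Difference of Gaussians with σ = 1.0 / 2.0 px, bracketing
  the PSF. Candidates are 3×3 in-slice local maxima above
  median + k·1.4826·MAD of that slice's filtered values (a tiny absolute
  floor, 10⁻⁶ ADU, suppresses numerical dust on flat slices). Median/MAD
  rather than mean/SD keeps the threshold immune to the spot tail.
- **Threshold k = 10.** Deliberately conservative: fields are mostly
  cell-free, so the global robust SD reflects read noise outside cells
  (≈0.8 filtered ADU) while in-cell shot noise is ≈2× larger. k = 10 puts
  the threshold ≈5 in-cell SDs up — false positives ≤2 per blank cell in
  validation — while a single emitter at the default S/N filters to ≈25,
  three-fold above threshold. Validated on synthetic scenes (recall ≥0.95
  at S/N 10 without autofluorescence; ≤5% median count error on the
  default scene).
- **Localization.** Gradient-based radial symmetry on a 7×7 patch at each
  detection's brightest slice. Gradients are computed at 2×2-block
  midpoints from the two diagonal differences, 3×3-mean smoothed; each
  defines a line through its midpoint along the gradient direction;
  weights are |g|² divided by the midpoint's distance to the
  gradient-magnitude centroid (clipped below at 0.1 px to bound the
  weight of a midpoint coinciding with the centroid). The center solves
  the 2×2 normal equations of the weighted point-to-line least squares;
  flat patches and collinear-gradient systems raise errors, and the
  caller falls back to the integer pixel. Localization is 2D only — z is
  reported as the brightest slice index, sufficient for counting.
  Accuracy: <0.01 px noiseless, ≈0.2 px RMS at peak S/N 5.
- **Linking.** Candidates sorted by descending filtered intensity (ties
  broken by (z, y, x)); each seed absorbs unclaimed candidates within
  2 px laterally in contiguous slices, tolerating up to 1 empty slice.
  Greedy rather than globally optimal: deterministic and adequate at
  counting densities (at the default density, ≈1% of emitters merge with
  a lateral neighbor, the dominant term in the ≈3% count error).
- **Aggregates.** The modal detection intensity — estimated by the
  half-sample mode, which is exact on constant data and ignores the
  bright tail — stands in for single-reporter brightness; detections
  >3× the mode are classed aggregates and excluded from counts (counting
  them as one complex is available as an option). Below 20 spots the mode
  is not estimated and everything is classed single-or-few, with a
  warning.
- **Tabulation.** A spot belongs to the retained region containing its
  rounded (x, y); spots in no retained region (including debris,
  aggregate-regions and border cells) are orphans. Counts + orphans =
  detections, always.

## Segmentation

Otsu threshold (absolute override available) on a 2D reference — max
projection by default — then 8-connected components. Area window 1500–
25000 px (~38–640 µm² at 160 nm pixels): undersized components are debris,
oversized ones aggregates; both are excluded, not split (purity over
recall — an aggregate counted as one cell corrupts two measurements).
Border-touching cells are excluded by default because partial footprints
bias counts. Because the synthetic autofluorescence tapers toward the cell
rim, Otsu footprints are slightly conservative there; count-accuracy
validation therefore uses the generator's ground-truth masks, and
segmentation is validated separately (≥18/20 cells retained at IoU > 0.5
on the default scene).

## Diffuse-fluorescence comparator

Per-slice background = mean over x-columns of the per-column minimum
pixel. Computed per slice (most literal reading of "each image" in a
z-stack, and robust to z-dependent haze); a max-projection mode is
exposed. Net diffuse signal = Σ_z (footprint sum − background_z × area),
with one 2D footprint through z. Values are not clipped at zero:
clipping would break linearity and bias the digitized-vs-diffuse S/N
comparison. The estimator is biased low by noise minima (the minimum of
~10³ noisy pixels sits several read-noise SDs below the mean), so
blank-scene nets are systematically positive; the suite bounds this bias
at 5 read-noise SDs per pixel-slice rather than asserting zero.

## Scoring

The index is computed via midranks in O((M+N) log(M+N)) and equals the
pairwise double sum exactly (ties contribute exactly ½ through average
ranks; the suite verifies exact equality against the brute-force loop).
p-values: exact enumeration for M·N ≤ 64 without ties, otherwise the
normal approximation with tie-corrected variance and continuity
correction; an all-tied comparison returns p = 1 with a warning. The
default alternative is two-sided, with a one-sided treated-lower option.
Multiple-drug adjustment is step-down Holm-Šidák over the drugs of one
panel (Holm and Bonferroni available); adjusted values are clipped to
[0, 1] and mapped back to input order. S/N = mean(signal)/mean(isotype
control), requiring a positive control mean. Outlier (insensitive-cell)
flags mark treated cells at or above the untreated mean; they are
reported, not modeled.

## Validation problem sizes

The suite favors scenes that exercise the full pipeline at moderate cost:
the default 20-cell, 1024²×60 scene (~2100 emitters) for count recovery
and segmentation; 512²-scale scenes for the S/N ordering (10 cells,
20 slices, abundance levels 40/20/8 versus an isotype floor of 3) and
false-positive floors; 1000-replicate M = N = 100 simulations for null
calibration; 500 Poisson replicates for localization. These sizes give
Monte-Carlo error comfortably inside every asserted tolerance.

## Known limitations

- Radial-symmetry localization degrades for overlapping spots; no
  multi-emitter fitting is attempted, so merged neighbors undercount.
- Aggregate discrimination assumes a unimodal single-reporter intensity
  distribution; heavily aggregated samples would bias the mode.
- The global per-slice threshold underestimates in-cell noise on fields
  with very high cell density (the robust statistics would then be
  dominated by in-cell pixels, lowering the effective margin).
- Segmentation is 2D; overlapping or touching cells are excluded rather
  than separated.
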