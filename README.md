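# qdcount

Digitized per-cell protein quantitation from 3D fluorescence microscopy:
count discrete nanoparticle (quantum-dot) tagged protein complexes in
single-cell z-stacks, compare the digitized readout against conventional
diffuse-fluorescence quantification, and score drug insensitivity across
cell populations with a distribution-free rank statistic.

Many signaling proteins — phosphoproteins especially — are present at such
low copy number that summed fluorescence per cell is dominated by
autofluorescence and camera background. Counting discrete reporter spots
instead of integrating intensity sidesteps that background: the per-cell
measurement becomes an integer number of detected complexes, and the
signal-to-noise against an isotype (no-primary-antibody) control improves
accordingly. The package is aimed at quantitative microscopists and
computational biologists who want the full counting chain — segmentation,
spot detection, sub-pixel localization, per-cell tabulation, population
scoring — with a synthetic-data generator providing exact ground truth for
validation.

## What it computes

**Digitized counting.** Each z-slice is band-pass filtered (difference of
Gaussians); robust-thresholded local maxima become spot candidates;
candidates from the several slices one emitter's PSF spans are linked into
a single detection; each detection is localized to sub-pixel precision by
gradient-based radial symmetry (every intensity gradient of a radially
symmetric spot points along a line through its center; the center is the
weighted least-squares point nearest all such lines). Detections much
brighter than the modal single-reporter intensity are classed as
aggregates and excluded. Counts are tabulated per segmented cell.

**Diffuse comparator.** Per cell, summed intensity over the whole stack
minus the field background × footprint area, where the background of each
field image is the mean over x-columns of the per-column minimum pixel.

**Population scoring.** For untreated per-cell values X = {x₁…x_M} and
treated Y = {y₁…y_N}, the *index of drug insensitivity* is

    index(X, Y) = P(X < Y) + ½·P(X = Y)
                ≈ (1/MN) Σᵢ Σⱼ [ δ(xᵢ < yⱼ) + ½·δ(xᵢ = yⱼ) ]

— the probability that a random treated cell out-measures a random
untreated cell. An index of 0.5 means treatment changed nothing (maximal
insensitivity); values near 0 mean essentially complete inhibition. The
companion Wilcoxon rank-sum test supplies p-values (U = MN·index exactly),
Holm-Šidák adjustment handles multi-drug panels, and the mean
phosphoresponse (mean(Y) − mean(X)) / sd(X) summarizes the shift in
untreated-σ units.

**Synthetic scenes.** Fields of non-overlapping round cells with
negative-binomial per-cell emitter counts, 3D Gaussian PSFs, smooth
spherically-tapered autofluorescence, Poisson shot noise, Gaussian read
noise and 16-bit quantization — with every emitter position and count
recorded, so detection accuracy is measurable, not assumed.

## Worked example

```sh
qdcount all --seed 1 --out demo
```

simulates an untreated and a treated field (20 cells each; treated
ground-truth counts drawn from the mixture model: 80% inhibition, 20%
insensitive subpopulation), counts spots in both, and scores the
comparison:

```
condition,M,N,index_of_insensitivity,rank_sum_U,p_value,p_adjusted,mean_phosphoresponse
treated,20,20,0.1725,69.0,0.0004129076033569179,0.0004129076033569179,-1.2611931261209384
```

Reading: of the 400 untreated/treated cell pairs, only 17.25% had the
treated cell higher — strong but incomplete inhibition (the insensitive
subpopulation keeps the index well above 0); the populations differ
significantly (p ≈ 4×10⁻⁴), and the treated mean sits 1.26 untreated-SDs
below the untreated mean. Per-cell tables, spot tables and region QC
tables are written alongside.

The same stages are available as `qdcount simulate`, `qdcount count` and
`qdcount compare`, and as plain library calls (`qdcount.simulate_scene`,
`qdcount.detect_spots`, `qdcount.compare_conditions`, …).

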