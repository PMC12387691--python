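# Methods

## Problem

Clinical classification from 3D structural brain MRI is usually done by a
3D network over millions of voxels or by 2D networks over slices chosen ad
hoc. `sliceinform` implements a middle path: (1) an automated,
orientation- and location-aware selection of *informative* 2D slices from
each 3D volume, and (2) a lightweight 2D classifier whose per-level
attention weights are interpretable. The pipeline reports how
classification performance depends on the slicing plane (axial, coronal,
sagittal) and on the anatomical position of the slice along that plane.

## Slice selection

Each volume axis is partitioned into fifteen contiguous, near-equal
segments (half-open index ranges; when the axis length is not divisible by
15 the leading segments absorb one extra slice each). Only the nine
central segments (1-based indices 4–12) are scored: edge segments contain
partial brain and carry little diagnostic content.

For every candidate slice `V` in a segment, a feature extractor `FE`
produces an activation map `A = FE(V) ∈ R^{H'×W'×C}`. Per channel, the
Shannon entropy of the intensity histogram is

    H(A_c) = −Σ_i P_i log2 P_i

with `P_i` the normalized count of the i-th of `n_bins` equal-width bins
spanning that channel's own [min, max]. The slice score is the mean over
channels, `H_mean(V) = (1/C) Σ_c H(A_c)`, and the segment's winner is the
argmax over its slices.

Numerical choices, each pinned in one place:

* entropy is in bits (base-2 logarithm); the base only rescales scores
  and cannot change any argmax;
* `n_bins = 256` by default; the histogram range is the channel's own
  [min, max], which makes the score invariant under affine intensity
  maps `αc + β, α > 0`;
* a constant channel short-circuits to entropy 0;
* ties in the argmax go to the lowest slice index, so selection is
  deterministic;
* slices are min–max normalized *per slice* (the histograms are per-slice
  quantities); a constant slice normalizes to all-zeros rather than
  erroring, so edge-of-brain slices cannot abort a run;
* grayscale planes are replicated to three channels for extractors and
  the classifier; resizing uses bilinear interpolation.

The default extractor is a fixed multi-scale filter bank (Sobel pairs,
Gaussian first derivatives, two Laplacian-of-Gaussian scales, Gaussian
smoothing, and the image itself; C = 8). It is deterministic, has no
learned weights, and needs no downloads, which keeps the whole test suite
self-contained; any callable obeying the extractor protocol — including a
pretrained CNN truncated at a convolutional feature map — can be plugged
in. Selection is per volume by default; a cohort mode that fixes, per
segment, the modal winning index across volumes is available
(`cohort_modal_winners`) for studies wanting one anatomically fixed slice
position across subjects.

Volumes are held in closest-to-RAS axis order, so sagittal = axis 0
(left–right), coronal = axis 1 (posterior–anterior), axial = axis 2
(inferior–superior). All indexing is 0-based with half-open ranges.

## Classifier

Three blocks, each: 3×3 depthwise convolution ('same' zero padding, one
filter per input channel), 1×1 pointwise convolution to 32/64/128
channels (a single bias per separable pair), ReLU, then 2×2 max-pooling
with floor semantics on odd sides (for the 150×150 reference input the
pooled sides are 75 → 37 → 18). There is no nonlinearity between the
depthwise and pointwise stages, so each pair is exactly a standard
convolution with a rank-1-per-channel kernel — this identity is what the
convolution oracle tests exploit.

Each block's pooled output is flattened and densely projected to a shared
32-dimensional space, then standardized per vector (subtract mean, divide
by standard deviation + 1e-6) so the three levels are statistically
comparable. A scorer shared across levels (32 → 64 ReLU → 1) yields one
logit per level; a softmax turns the three logits into attention weights
on the 2-simplex; the fused representation `Σ w_b f_b` feeds a single
sigmoid unit. Classification threshold is 0.5. The per-item weights are
returned by every forward pass: averaged over a cohort they say whether
low- (block 1), mid- (block 2), or high-level (block 3) features carried
the decision.

The network is implemented directly in NumPy with explicit
backpropagation (verified against central-difference gradients to 1e-4
relative) and trained with Adam (lr 0.001, β = 0.9/0.999), binary
cross-entropy, 20 epochs, batch size 32. Initialization uses He-scaled
normals from a seeded generator; shuffling is seeded; training is
bit-reproducible. float64 is the default precision and is used by all
correctness tests; float32 is available for large sweeps and changes no
qualitative result.

## Operation counting

For a convolution with kernel `D_k`, `M` input channels, `N` output
channels and output side `D_f`, the multiply–accumulate costs are

    standard: D_k²·M·N·D_f²        separable: D_k²·M·D_f² + M·N·D_f²

so the separable/standard ratio is exactly `1/N + 1/D_k²`. MACs expand to
FLOPs under one pinned convention: 2 FLOPs per MAC for convolutions and
dense layers, +1 per bias addition (one bias per separable pair, carried
by the pointwise stage, and one per dense output), 4 comparison ops per
2×2 max-pool output, with elementwise activations, softmax, and the
vector standardization uncounted. Under this convention the reference
configuration totals 78,108,028 FLOPs, within 0.1% of the independently
reported total for this architecture (78,102,649). Since per-block filter
counts, the attention hidden width, and the original counting tool are
not published, the filter doubling scheme (32, 64, 128) and the
convention above were calibrated against that anchor; an enumeration of
defensible conventions (bias placement, ReLU counting, 0–4 pooling ops
per output, one- vs two-layer scorers, hidden widths 16–256) brings no
convention to exact agreement, so the MAC-level per-layer breakdown is
the binding contract and the op-level total is documented as the pinned
convention's output.

## Evaluation protocol

Three-way splits follow an 80/10/10 convention with train = floor(0.8 n),
test = ceil(0.1 n), validation = remainder — for n = 1125 this gives
900/112/113. Cross-validation is stratified and seeded: each of the k
folds draws its own stratified 10% test holdout, then a stratified k-fold
on the remainder supplies that fold's validation part. This resolves the
tension between "5-fold CV" and "10% held out for testing in each fold"
(a plain 5-fold would hold out 20%); a plain k-fold mode is available by
flag. Splitting is per item; with multiple scans per subject this risks
subject leakage, which phantom cohorts avoid by construction (one volume
per synthetic subject).

Metrics: accuracy, precision, sensitivity, specificity, F1 (harmonic
mean of precision and sensitivity), and AUC as the trapezoidal area under
the ROC built from the continuous sigmoid scores (equal to the normalized
Mann–Whitney U statistic with ties counted one half — the test suite
checks this equivalence against a brute-force pairwise oracle). Ratios
with zero denominators are reported as NaN with a warning, never silently
as 0; fold aggregation is an unweighted NaN-aware mean.

The accuracy grid trains one freshly initialized model per
(orientation, segment) cell on that cell's selected slices, per fold.
Every model seed derives from the master seed and the cell's position via
`SeedSequence`, so results are independent of evaluation order, and the
grid's accuracy argmax (ties resolved toward the first cell in sorted
(orientation, segment) order) is deterministic.

## Phantom cohorts

The generator emulates skull-stripped, intensity-normalized T1 volumes:
a smooth ellipsoidal foreground at intensity ≈ 0.7 with a mild radial
falloff and Gaussian-blurred boundary (σ = 1.5 voxels) on near-zero
background. The positive class receives, only inside the intersection of
the brain mask with one configurable orientation+segment slab, an
intensity offset of −0.3 (the default `effect_amplitude`, emulating
atrophy-like signal loss) plus i.i.d. texture of SD 0.1. Both classes
receive a per-subject global intensity gain (SD 0.05) and voxelwise
Gaussian noise (SD 0.02). The effect slab is computed with the same
fifteen-segment partition arithmetic the selection pipeline uses, so
generator and analysis share one source of truth for segment coordinates.
Effect-noise draws happen for both classes so the RNG streams stay
aligned: a zero-amplitude, zero-texture cohort is identical in law across
classes, which the null tests exploit.

What the phantoms do *not* model: anatomy (gyri, tissue classes,
hemispheric asymmetry), scanner artifacts, registration error, or
multiple scans per subject. Passing the recovery test therefore shows
that the pipeline's selection, training, and bookkeeping correctly
localize a planted, spatially confined class difference — not that any
particular accuracy level transfers to clinical data. One physical
consequence worth knowing: because the effect region is a 3D slab, slices
of the *other* two orientations cross it and also carry (weaker, partial)
signal, so their grid cells legitimately score above chance; the planted
cell is still the argmax because its slices carry the effect over their
full extent.

## Problem sizes used by the test suite

The reference configuration (150×150×3, filters 32/64/128) is the
package default and is what the operation-count accountant reports.
Training-based tests use reduced configurations chosen once: phantom
cohorts of 64³ voxels with 20 subjects per class, model input 32×32 with
filters (8, 16, 32), 2 CV folds, 20 epochs, float32 — a scale at which
the planted-effect recovery runs in a few minutes on one CPU while
leaving every architectural element (three DSC blocks, projections,
attention, training dynamics) in place. Unit tests use still smaller
16×16 models that train in well under a second.

## Known limitations

* The extractor that defined "activation maps" in the original study was
  a pretrained CNN; the built-in filter bank is a deterministic stand-in
  with the same contract. Rankings can differ between extractors.
* Histogram entropy with per-channel [min, max] range is sensitive to
  heavy-tailed activations: a few extreme values compress the bulk of the
  histogram and can *lower* entropy. The scale-invariance property is
  exact, but outlier robustness is not claimed.
* The 80/10/10 rounding convention reproduces only the n = 1125 anchor;
  published counts for other cohort sizes are mutually inconsistent under
  any single rounding rule and are not reproduced.
* Training is full-batch-sequential NumPy on CPU; it is meant for
  phantom-scale experiments and method development, not for large imaging
  cohorts.
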