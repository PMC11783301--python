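# Methods

## Problem and model

Thin, branching, tubular structures — retinal vessels, neuronal membranes,
endoplasmic reticulum — are segmented poorly by volumetric losses alone: a
handful of mispredicted pixels can sever a branch (a *fracture*) while barely
moving Dice.  This package implements a semi-supervised fracture-attention
model (SSFA): two segmentation networks with identical architecture and
different initializations are trained jointly, with cross pseudo supervision
(CPS) on unlabeled images and an iteratively updated *fracture-attention map*
(FA map) as an extra input channel group that directs both networks toward
fracture-prone regions.

The total objective at epoch r of R is

    L_total = L_sup + λ(r) · L_unsup,        λ(r) = λ_max · r / R,

where `L_sup = Dice(p¹, y) + Dice(p², y)` on labeled images and
`L_unsup = Dice(p¹, ŷ²) + Dice(p², ŷ¹)` on unlabeled images; `ŷ¹, ŷ²` are the
hard (argmax, detached) pseudo-labels of the opposite branch.  All four terms
are soft Dice losses (ε = 1e-5).  λ ramps linearly: the model leans on the
labeled data early and increasingly exploits the unlabeled pool.

## The fracture-attention map

The FA map of an image is a 3-channel per-pixel prior in [0, 1]:

* **TS maps (two channels, one per branch prediction).**  For a binarized
  prediction P, compute its skeleton S and Euclidean distance transform D
  (an isolated foreground pixel has value 1).  With d_min/d_max the extrema
  of D over skeleton pixels, a ladder of L thresholds
  `t_l = d_min + l·(d_max − d_min)/L` is applied: at each level, pixels with
  D < t_l are deleted from P and the remainder re-skeletonized to S_l.  A
  skeleton pixel *fails* level l when no pixel of S_l lies within Chebyshev
  radius 1 of it; each foreground pixel inherits the fail count of its
  nearest skeleton pixel, divided by L.  Thin branches disappear at low
  thresholds, fail many levels and score near 1; thick trunks score near 0.
  Values are multiples of 1/L.  Default L = 10.
* **DS map (one channel).**  Marks semantic disagreement between the two
  branch predictions: a skeleton pixel of one prediction with no skeleton
  pixel of the other within radius ρ is a *mismatch*; pixels of the symmetric
  difference whose nearest skeleton pixel is a mismatch are set to 1.
  ρ = 2 px suppresses pure boundary jitter (whose skeletons coincide) while
  keeping whole missing or extra branches.

Per image the map at epoch r is the non-recursive blend

    A_r = (1 − k) · A_0 + k · Â_r,       k ∈ [0, 1],

of the *initial* map A_0 and the map Â_r rebuilt from the current epoch's two
binarized predictions.  A_0 comes from a plain supervised UNet trained on the
labeled images alone: its single prediction fills both TS channels and the DS
channel starts at zero (one prediction cannot disagree with itself).  k = 0
freezes the map, k = 1 replaces it each epoch.

### Interpretive choices

The level-combination rule ("pixel-wise addition" of per-level maps), the
difference-matching operator behind the TS and DS maps, and the blend's
non-recursive reading (always anchored at A_0, not the previous epoch's map)
are under-determined in the method's narrative description; the definitions
above are this package's declared reading, chosen to be simple, exactly
testable and stable in range.  Likewise both networks receive the same shared
3-channel map rather than branch-specific maps.

## Architecture

A UNet with two encoder streams: a Raw Image Encoder (1 input channel) and an
FA Encoder (3 channels).  At every resolution level the streams are fused by
element-wise multiplication *before* downsampling; the fused product feeds
the skip connection and the next image-encoder level while the FA stream
pools its own un-fused features.  The FA stream's final per-level activation
is `1 + tanh(·)` (range (0, 2)), so an all-zero attention map multiplies by
≈1 instead of annihilating the image features — important at the cold start,
when an untrained init network can output an empty mask.  Variants: `single`
(fusion at the first level only), `channel` (FA map concatenated as input
channels, no second encoder), `none` (plain UNet; pretraining/baseline).
Blocks are 3×3 conv → group norm → ReLU (twice), max-pool down, bilinear up
with skip concatenation, 1×1 conv head with channel softmax.  Group
normalization is used throughout because the shipped batch sizes (4–16) are
too small for stable batch statistics.

The networks are trained with SGD (momentum 0.9, weight decay 5e-5); the
reference schedule is lr 0.1 halved every 25 epochs, batch 16, 100 epochs.
λ_max = 3.0 and k = 0.6 are the defaults, appropriate for small labeled sets.

## Inference

Two-stage: build the initial FA map from the supervised init network
(TS1 = TS2, DS = 0), run both branches, rebuild the map from their two
predictions with the configured k, then re-run the branch that achieved the
better validation Dice (on a held-out 20% of the labeled images, fixed by the
data seed) and binarize at 0.5.  All binarization thresholds in the package
are 0.5.

## Fracture Rate

The topological graph of a mask is built from its skeleton: nodes at skeleton
pixels with ≠ 2 neighbors (8-connectivity, adjacent node pixels clustered),
edges the traced pixel paths between them, isolated cycles one self-loop
edge.  Leaf edges shorter than 5 px are pruned as skeletonization artifacts
(identically for prediction and truth) and edges shorter than 3 px are
contracted.  An edge of the ground-truth graph is **fractured** when some
pixel of its middle segment — the path minus min(δ, ⌊len/3⌋) pixels at each
end, since endpoint neighborhoods legitimately shift between skeletons — has
no prediction-skeleton pixel within Euclidean distance δ (default δ = 5 px).

    FR = 100 · N_F / N_Y   [%],

with N_Y the ground-truth edge count and N_F the fractured count.  Matching
is against the prediction's *skeleton*, not its raw foreground: a thin
fracture bridged by a blob should still count.  The fast implementation uses
one distance transform of the prediction skeleton; tests pin its per-edge
verdicts to a brute-force all-pairs scan.

Other metrics: clDice (harmonic mean of skeleton-precision |skel(P)∩Y|/|skel(P)|
and skeleton-sensitivity |skel(Y)∩P|/|skel(Y)|; 1 when both masks are empty, 0
when exactly one is), Betti errors (β0 = 8-connected foreground components;
β1 = 4-connected background components − 1, the standard duality pair;
errors are absolute differences, β-error their sum) and accuracy/Dice/Jaccard
(both-empty masks score Dice = Jaccard = 1).

## Synthetic phantoms

Real tubular datasets are large and external, so every component is exercised
on generated phantoms with *known* centerline topology.  A phantom is a set
of branching centerline trees: a trunk random walk with curvature bound
(σ = 0.08 rad/step), children spawned off the trunk with probability 0.05
per step at 60–110% of the local direction offset, radius tapering linearly
with a sinusoidal modulation (so the TS ladder has several occupied levels),
everything clipped to ≥ 1 px.  Collision tests against already-drawn
structure keep trees and siblings from crossing, and spawn points keep clear
of branch ends by one tube radius plus the spur-pruning length, so the
planted segment count matches the skeleton-graph edge count (within ±2 for
≥ 90% of seeds — junction clusters can still merge on thick trunks).  The
mask is the union of swept discs; the image is a smoothed two-level rendering
(background 0.15, foreground 0.85, Gaussian σ = 1) with additive Gaussian
noise and optional low-contrast discs (contrast × [0.2, 0.6], mask untouched)
that mimic semantically ambiguous regions and provoke exactly the prediction
disagreement the DS map is built to capture.

`inject_fractures` cuts a gap of `gap_px` (default 15 > 2δ) centered on the
midpoint of a chosen edge's skeleton path, clearing only pixels owned by that
edge's tube and only on edges whose gap neighborhood is > δ + 2 px from every
other edge.  By construction the broken edge's middle segment is uncovered
and no other edge is touched, so FR = 100·m/N_Y exactly — the metric's oracle.

What the phantoms do **not** model: modality-specific texture (PSFs, EM
noise), anisotropy, touching/overlapping tubes, 3-D structure, annotation
noise.  Passing tests therefore demonstrate correctness of the mechanics and
the direction of the semi-supervised effect at desk scale, not clinical-grade
performance on real data.

## Desk-scale profile and problem sizes

The shipped CPU profile (`TrainConfig.desk_profile()`) uses 64×64 phantoms
(two trees, radii 1.5–4 px, noise 0.05), 8 base channels, depth 3, batch 4,
20 epochs, group norm, with the standard split 8 labeled / 32 unlabeled /
8 test.  These sizes are chosen so a full baseline-plus-SSFA comparison runs
in minutes on one CPU core while still containing junctions, width variation
and ambiguity regions.  The networks run on a small numpy reverse-mode
autodiff engine written for this package (`ssfa.nn`, NHWC layout,
convolutions as nine batched BLAS matmuls); its gradients are verified
against finite differences in the test suite, and all computation is
deterministic given the seeds.

## Numerical conventions

* Coordinates are (row, col), 0-based, top-left origin.
* Distance transforms are exact Euclidean (`scipy.ndimage`); "within δ"
  means ≤ δ.
* Max-pool ties resolve to the first element; bilinear upsampling uses the
  align_corners=False convention.
* Degenerate inputs: empty masks give empty skeletons and zero TS/DS maps;
  `distance_map` and `fracture_rate` raise on empty inputs for which their
  outputs would be undefined.
* λ is stepped per epoch (constant within an epoch); FA maps are rebuilt once
  per epoch from a dedicated clean (un-augmented) forward pass per image, so
  the stored maps stay spatially registered with their images.
* Geometric augmentations (flips, right-angle rotations, transposition) are
  applied identically to image, mask and FA channels.

## Known limitations

* 2-D only; no 3-D skeletons or volumes.
* The Betti-1 count is combinatorial (background components), not a persistent
  homology matching; it counts holes, not their correspondence.
* The skeleton-graph builder targets tubular topology; space-filling or
  blob-like masks produce graphs whose edges are not meaningful branches.
* At desk scale both the baseline and the semi-supervised model can saturate
  the easy phantom conditions (FR ≈ 0 for both); the benefit criterion is
  directional (≤), not a strict improvement.
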