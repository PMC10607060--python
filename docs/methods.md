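# Methods

## Problem setting

Larvae of several lepidopteran field pests (fall armyworm and its common
look-alikes) are close in colour, texture, shape and habitat, which makes
species-level detection in field imagery a fine-grained problem: the hard
part is not finding an elongated object on a leaf but deciding *which* of
five nearly identical species it is, and localising it under occlusion and
uneven lighting. `larvadet` implements a feature-refinement recipe for
two-stage detectors aimed at exactly this regime, together with a seeded
synthetic-scene generator so that every stage is testable without field
data, and a COCO-style evaluator.

## The detector

The pipeline is the classic region-proposal design with three refinements.

**Backbone and pyramids.** A four-stage CNN emits C2..C5 at strides
4/8/16/32. Each level is projected to a unified width by a 1×1 convolution
φᵢ. The projected (optionally enhanced) levels form the lateral pyramid
M2..M5; a standard top-down pathway (nearest-neighbour 2× upsampling, add,
3×3 smoothing) produces P2..P5, and a stride-2 subsample of P5 gives P6,
used only for proposal generation. Any module returning four feature maps at
those strides can replace the backbone.

**Context feature enhancement (CFEM).** Per level, an atrous spatial
pyramid pooling (ASPP) block over φᵢ(Cᵢ) produces attention logits; with
Aᵢ = σ(f_aspp(φᵢ(Cᵢ))) the enhanced feature is

    Mᵢ = (1 + Aᵢ) ⊙ φᵢ(Cᵢ).

The residual form bounds the output between 1× and 2× the projected
feature, so context can emphasise but never erase a response. The ASPP
branch set is the canonical one: a 1×1 convolution, two 3×3 atrous
convolutions at rates r and 2r, and a global-average image-pool branch
(switchable via `cfem_image_pool`, since reasonable ASPP variants differ
here); branches are concatenated and projected back by a zero-initialised
1×1 convolution, so an untrained block starts at A = 0.5 everywhere — a
mild uniform boost, a neutral start. The attention map is full-channel
(the multiplication is element-wise, not a single spatial map broadcast).
The sampling rate defaults to r = 2; r = 1 reduces the atrous branches to
ordinary convolutions and large r correlates the object with distant
background, which is why a small rate is the default. Levels never mix:
each has its own projection and ASPP.

**Adaptive RoI fusion (RFFM).** Instead of assigning each proposal to one
pyramid level by its size, every proposal is RoIAligned (7×7, 2×2 samples
per bin, half-pixel alignment) from *all four* levels. The concatenated
stack R_c (4·C channels) is reduced to C channels by a 1×1 convolution,
passed through ReLU and a size-preserving 3×3 convolution to 4 channels,
and a sigmoid yields one 7×7 spatial weight map per level:

    w = σ(ϕ₃(ψ(ϕ₁(R_c)))),      R = Σᵢ wᵢ ⊙ Rᵢ.

Weights are independent sigmoids — deliberately not softmax-normalised
across levels, because the formulation calls for a sigmoid and the two
choices change the scale of the fused feature. The weight maps broadcast
over channels (spatial-only weighting). ϕ₃ is zero-initialised so an
untrained module fuses with uniform weight 0.5. With fusion disabled the
head falls back to the canonical single-level assignment
(k = ⌊4 + log₂(√area/224)⌋ clamped to [2,5]).

**Task separation (TSM).** Classification and localization get *different*
fused features from two independent fusion modules: classification reads
the top-down pyramid P2..P5 (stronger semantics), localization reads the
lateral pyramid M2..M5 (richer detail). Each branch is two fully connected
layers (default width 1024); classification ends in K+1 logits,
localization in 4·K per-class deltas. All four (classification source,
localization source) pairings are reachable through `cls_source` /
`loc_source`, spanning the 2×2 configuration grid; (P for classification,
M for localization) is the default. The branches share no parameters, so
the classification loss has exactly zero gradient on localization-branch
parameters and vice versa — this decoupling is asserted numerically in the
tests. No feature-consistency penalty is applied between the branches: the
notion is not operationalised in the source formulation, so the package
deliberately implements separation as plain architectural decoupling.
With separation disabled the head is the conventional one: a shared tower
with separate final layers.

**Losses and training.** Cross-entropy over sampled proposals for
classification; Smooth L1 (0.5x² below |x| = 1, |x| − 0.5 above) over
positive proposals' deltas for localization, normalised by the number of
sampled proposals; unit loss weights. The proposal stage uses the standard
anchor losses (binary cross-entropy on objectness, Smooth L1 on positive
anchors). Anchors: one size per level {32,64,128,256,512} × ratios
{0.5,1,2}; RPN matching at IoU 0.7/0.3 plus a best-anchor-per-ground-truth
rule; head matching at IoU 0.5 with 512 sampled RoIs at 25 % positives
(ground-truth boxes are appended to the proposals during training).
Per-class box regression uses the standard delta encoding with target
normalisation stds (0.1, 0.1, 0.2, 0.2). The optimiser is SGD with
momentum 0.9, weight decay 1e-4, learning rate 0.005, batch 2, 12 epochs
with ×0.1 decay after epochs 8 and 11, and horizontal flips with
probability 0.5 — the full-scale recipe. Native image sizes are kept; the
(1333, 800) cap applies only to inputs that exceed it.

Only a single refined head is implemented. A cascade of refinement stages
exists in the configuration surface (`cascade_stages`) as a stub that
raises `NotImplementedError` for values above 1: the ablation-grade
single-head setting covers every novel module while staying tractable on a
CPU.

**Compute core.** The package carries its own reverse-mode automatic
differentiation engine on numpy (`larvadet.nn`): im2col convolution with
stride/dilation, RoIAlign with an exact bilinear-scatter backward pass,
nearest-neighbour resampling, the losses above, and SGD. Everything is
float64 and single-threaded apart from BLAS. Backward passes are verified
against central finite differences in the test suite.

## The synthetic scene generator

The generator fabricates the statistical structure of a similar-pest field
dataset rather than its photographic appearance. Each larva is a curved
capsule: a random smoothly-turning spine of unit length with a tapered
half-width profile, scaled so its *analytic* bounding box (spine ± local
width) hits a target area, then rasterised with lateral cylinder shading,
longitudinal stripes (sinusoidal in arclength), and a dark head marker.
Class appearance is a 5-vector (hue, stripe frequency, stripe contrast,
head size, body aspect); the K classes sit at archetype + (1 − s)·offset
with deterministic per-class offsets, so the `similarity` knob s scales all
pairwise appearance distances linearly — at s near 1 the classes are nearly
identical, and a fixed crop classifier demonstrably degrades (a directional
test in the suite). Backgrounds are smoothed-noise vegetation palettes with
leaf/stem clutter shapes; `clutter_level` sets their density and contrast.
Occluders (leaf-like ellipses) are drawn over an instance with probability
`occlusion_prob`; `illumination_jitter` controls a global gain and a linear
shading gradient.

Scale mixture: an instance is medium (COCO sense, area in [32², 96²]) with
probability `scale_mix` = 0.396 by default and large otherwise — the
mixture of the dataset being emulated, which contains no small instances,
so small-scale generation has probability 0. Target box areas are sampled
with a safety margin inside each bin ([1700, 8100] and [11800, ≤40000] px²)
so that integer rounding of the box can never cross a bin boundary; the
emitted annotation *is* the analytic box (the raster mask is constrained
inside it), which makes the scale statistics exact and lets them be
computed from layouts without rasterising. Scenes carry 1–2 instances by
default (the emulated dataset averages ≈1.05 instances per image; the exact
per-image distribution is not published, so this is an inference). Datasets
are stratified: each image holds a single species, `n_per_class` images per
class, split per class with train count ⌊0.8·n + 0.5⌋ (published per-class
splits are not consistent with any single rounding rule, so one rule is
fixed; it reproduces the 1007 → 806/201 row exactly). Everything is seeded:
identical specs give byte-identical PNG and XML output.

What the generator does *not* emulate: real foliage texture and specularity,
body segmentation and legs, pose articulation beyond spine curvature,
camera noise, and inter-class differences that are not monotone in a single
similarity parameter. Passing tests therefore show that the architecture
can learn and the pipeline is correct end to end — not that the method
reaches any particular accuracy on real field imagery.

## Evaluation

AP uses 101-point interpolation (precision at recall r = max precision at
recall ≥ r), pooled over images per class; mAP averages over classes and
the ten IoU thresholds 0.50:0.05:0.95. The interpolation scheme follows the
COCO convention, consistent with the COCO size bins used throughout.
mRecall is realised as the class mean over the same thresholds of the
maximum achieved recall with at most 100 detections per image — the
published definition is verbal, so this reading is recorded here rather
than asserted as canonical. Per-scale AP (AP_M, AP_L) restricts ground
truths to a size bin with ignore semantics: detections matched to
out-of-bin ground truths, and unmatched detections whose own box is out of
bin, are dropped rather than counted as false positives. A class with no
ground truths has undefined AP and is excluded from the means. Matching is
greedy by descending score against the best-IoU *unmatched* ground truth,
with (score, index) as the deterministic tie-break. The confusion matrix
(confidence 0.5, IoU 0.5) matches class-agnostically first and labels the
cells afterwards, so wrong-species detections produce off-diagonal entries,
missed ground truths fall into the background column, and unmatched
detections charge the background row; rows are reported as percentages.

## Desk-scale study conditions

Numbers in the README and the acceptance script come from the tiny preset,
chosen so a full training run fits in minutes on one CPU: 128×128 canvas,
2 classes, medium-only scale mixture (large instances do not fit that
canvas), similarity 0.5, clutter 0.3, no occlusion; backbone widths
(8,16,32,64), pyramid width 32, head width 128, anchor sizes 16..256,
96 sampled RoIs, 200/100 proposals, constant learning rate 0.02. The
overfit check trains the full model (enhancement + fusion + separation) for
400 iterations of batch 2 on 20 scenes and evaluates on those same scenes;
training from random initialisation at this scale is noisy, so the check is
stochastic by design (two of three fixed seeds must reach mAP@0.50 ≥ 50 %
with decreasing smoothed loss). The ablation grid runs all six module
on/off combinations for one step with further-reduced proposal counts;
parameter counts are asserted to grow when modules are enabled, but their
absolute values are specific to this small backbone and are not meaningful
beyond the monotonicity.

## Known limitations

- No normalisation layers; training from scratch beyond the desk scale
  would likely need them (the full-scale recipe assumes a pretrained
  backbone, which is out of scope here).
- The numpy engine is single-image (batching is a gradient-accumulation
  loop) and CPU-bound; it is a correctness-first implementation.
- The cascade configuration is a stub; only the single refined head is a
  tested path.
- Absolute detection accuracy on real field imagery is not claimed
  anywhere: the synthetic scenes are a statistical stand-in, not a
  photorealistic one.
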