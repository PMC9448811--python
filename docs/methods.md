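# Methods

This note records the modelling choices behind `hccanet`: what each stage
computes, which parameters matter, what the synthetic benchmark does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## The attention mechanism

Given a feature map FM ∈ R^{H×W×C}, one selective-kernel (SK) block at
reduction ratio r computes two channel-preserving branch responses with
3×3 and 5×5 kernels (stride 1, zero 'same' padding so H×W is preserved),
sums them, global-average-pools to a C-vector, and passes it through the
squeeze-excitation bottleneck C → ⌈C/r⌉ → C (rectifier between the two
affine maps, sigmoid at the end). The result Mₐ gates the 3×3 branch and
its complement M_b = 1 − Mₐ gates the 5×5 branch:

    FM_c = Mₐ ⊗ U₃ ⊕ M_b ⊗ U₅.

Two readings of this block were possible. A literal per-channel gate on
FM itself — (Mₐ ⊗ FM) ⊕ (M_b ⊗ FM) — collapses to FM because the gates
are complementary, making the block a no-op; the implemented form gates
the two branch responses, which is the selective-kernel semantics the
block is named after, and is the reading under which every neuron adapts
its receptive-field scale. The gate is taken to be per-channel (length
C), not per-position.

The full MCCBAM block runs three SK blocks in parallel at r = 4, 8, 16,
concatenates the refined maps along channels (H×W×3C), multiplies the
concatenation elementwise with FM replicated three times along channels,
computes a 7×7 spatial attention map from that product, and multiplies
the map back in. The output is H×W×3C. The replication and the choice to
drive the spatial map from the concatenated product (rather than the
original FM) are forced by the one unambiguous shape constraint on the
block — a 3C-channel output — since an elementwise product of a
3C-channel and a C-channel array is otherwise undefined. The bottleneck
uses ⌈C/r⌉ so ratios larger than C still leave at least one hidden unit;
a ratio producing an empty bottleneck is rejected.

Reduction ratios (4, 8, 16), branch kernels (3, 5) and the 7×7 spatial
kernel are configurable through `MCCBAMConfig`; the defaults are the
mechanism's defining values and there is no reason to change them except
for ablation.

## Architecture

The backbone is the standard VGG16 convolutional stack
((64×2, 128×2, 256×3, 512×3, 512×3) with 2×2 max-pooling after each
stage). `width_multiplier` scales every stage's channel count (minimum
one channel) so the full topology can be trained from scratch on one
CPU; the topology, not the width, is what the attention block's
contracts depend on, and the 4C fusion relation holds at any width.
Layers before a named freeze boundary are non-trainable; the default
boundary `Block_Conv3` is interpreted as the first convolution of the
third block, i.e. blocks one and two are frozen — the common
fine-tuning convention for this backbone. The boundary name is
configurable, and an unknown name is an error rather than a silent
default.

Loading externally pretrained backbone weights is supported through
`BackboneConfig(pretrained=True, weights_path=...)` as an optional hook;
nothing in the package or its tests requires pretrained weights, and
without them the backbone initialises from the seeded scheme below.

The head is the smallest standard choice: global average pooling over
the fused 4C-channel map followed by one affine layer to three logits
and softmax. Fusion is channel concatenation; addition would force the
attention output back to C channels and contradict the 3C output
contract of the attention block.

## Initialisation and optimisation

Weights are initialised from a seed-controlled uniform fan-in
distribution with rectifier gain, U(−√(6/fan_in), +√(6/fan_in))
(variance 2/fan_in). A plain 1/√fan_in uniform scale loses a constant
factor per layer and visibly starves the thirteenth layer of signal
(activations ~10⁻⁶ at depth); the rectifier-gain variant keeps
activation magnitudes near unity through the whole stack, which matters
here because the attention branch multiplies activations pairwise.

Training is minibatch Adam with β₁ = 0.9, β₂ = 0.99, learning rate
0.005, categorical cross-entropy; defaults are 100 epochs at batch
size 32, overridden to desk scale (10 epochs, batch 16) in the bundled
experiments. The training loop applies global-norm gradient clipping
(default threshold 1.0, configurable, `None` disables). This is a
numerical-stability choice: at learning rate 0.005 a from-scratch
width-shrunk backbone takes parameter steps large enough to kill
rectifier units wholesale, and runs intermittently collapse to the
uniform predictor without clipping; with it, the prescribed optimizer
settings train reliably. There is no early stopping; when a validation
set is supplied, the parameters of the best-validation-accuracy epoch
are retained and restored after the final epoch. A non-finite loss
aborts training with `TrainingDiverged` rather than continuing silently.

## Preprocessing

Denoising precedes resizing, which precedes standardization. Four filter
families are implemented behind one `FilterSpec` surface — mean, median,
gaussian and bilateral — each applied per channel with edge-replicated
borders, swept over kernel sizes 3/5/7 when comparing filters. The
gaussian filter uses an explicit k×k kernel normalised to sum to one,
with sigma derived from the kernel size by the common convention
σ = 0.3·((k−1)/2 − 1) + 0.8 when not given; bilateral sigmas default to
75 (intensity units) and 75 (pixels). Resizing is bilinear with
half-pixel-center sampling and edge clamping — conventions pinned
explicitly so the operation has a closed form. Standardization is
per-feature zero-mean/unit-variance ("divide by the standard deviation";
dividing by the variance would contradict the unit-variance property the
transform is defined by), fitted on the training split only and applied
unchanged to validation and test data; zero-variance features map to
zero.

## The synthetic benchmark

The generator emulates the grading geometry, not H&E appearance: each
image is a pink mottled background on which ring-shaped "glands" (purple
annulus wall, pale lumen) are placed at random until the fraction of
area covered by gland disks reaches a target drawn uniformly inside the
grade's coverage interval — (0.95, 1] for grade I, [0.50, 0.95] for II,
[0.05, 0.50) for III, mirroring the >95% / 50–95% / 5–50% glandular
differentiation definitions. A ground-truth boolean mask records gland
coverage, so the label is correct by construction and coverage always
lies inside the requested interval (the target keeps a margin from the
interval edges and trailing glands shrink so the last placement cannot
overshoot). Pixel noise is additive gaussian, default sd 8 on the 0–255
scale. Every image is deterministic in (dataset seed, grade, per-image
index), and six consecutive images per grade share a source identifier,
mirroring multiple patches cut from one tissue section.

What this does not emulate: stain variability, nuclear texture, gland
irregularity, or any within-class structure beyond coverage. Passing
tests on this data therefore demonstrate that the pipeline is wired
correctly and can learn a texture-density signal — not that the
architecture reaches any particular accuracy on clinical images.

The archive-scale configuration is 210 images per grade (630 total),
split 8:1:1 with stratification (floor allocation, remainders to the
training split: 504/63/63), and the training split augmented to exactly
4500 sheets, 1500 per grade, by rotation (±30°), random cropping
(80–100% of the side, resized back) and scaling (0.9–1.1, center-cropped
or edge-padded back). "Rotation, cropping, scaling" is treated as the
closed operation set. Every variant keeps its source's label and records
its source and operation parameters in an augmentation log. Splitting is
image-level by default — six patches of one source can straddle subsets,
a known leakage channel at patch level — and an optional
`group_key="source"` keeps sources intact at the cost of exact subset
sizes (deviations beyond 10% of a class are warned about).

## Evaluation

`compute_metrics` tallies the 3×3 confusion matrix and reports per-class
precision TP/(TP+FP), recall TP/(TP+FN), F1, and overall accuracy;
zero-denominator rates are reported as 0 and flagged rather than raised.
One-vs-rest AUC uses the Mann–Whitney rank statistic with midrank tie
handling — AUC_k = (R⁺ − n⁺(n⁺+1)/2)/(n⁺n⁻) — which is exactly the
fraction of correctly ordered positive/negative pairs (ties half); the
macro average is the unweighted mean over classes with defined AUC, a
class absent from the truth being flagged rather than averaged. Both a
fixed 8:1:1 split ("headline" mode) and stratified five-fold
cross-validation are implemented; the CV mode reports per-fold metrics
plus mean and standard deviation.

## Grad-CAM

The class score is the pre-softmax logit (softmax gradients saturate and
the logit makes the map invariant to adding a constant to all logits).
Channel weights are the spatial means of ∂score/∂A at the chosen
feature map A; the heatmap is the rectified weighted channel sum,
bilinearly upsampled to input resolution and min-max normalised
per image, with an all-zero map (vanishing gradients) returned as an
explicit flagged zero rather than a divide-by-zero. The default target
layer is the fused map — the network's final convolutional
representation — and any backbone convolution or the attention output
can be targeted instead. Overlays use a blue→white→red colormap chosen
so rendered redness is monotone in the heat value (the heat peak is
always the reddest pixel), blended at a configurable alpha.

## Numerical details and edge cases

- All computation is float64 on the package's numpy autodiff engine;
  convolutions are stride-1 zero-padded 'same' throughout the model, and
  max-pooling breaks ties by first occurrence.
- M_b is computed as 1 − Mₐ, so Mₐ + M_b = 1 holds exactly in floats.
  Saturated sigmoids can round to exactly 0 or 1; the functional API
  clamps gates and spatial maps into [10⁻¹², 1 − 10⁻¹²] to preserve the
  open-interval contract (far below the 10⁻⁵ tolerance at which the
  operations are checked against straight-line transcriptions of their
  equations).
- Checkpoints are numpy `.npz` archives of the parameter list;
  architecture summaries (layer names, shapes, trainable flags) are JSON.
- Desk-scale problem sizes used by the bundled experiments, chosen once:
  64×64 synthetic images, width multiplier 1/8 (stage widths
  8/16/32/64/64), batch 16, 10 epochs; the learning-sanity fixture uses
  the generator's wide-margin coverage sub-intervals
  (I (0.95, 1], II (0.55, 0.75), III (0.05, 0.25)) because near the
  0.95 boundary grade I and II images are intrinsically ambiguous and no
  short training run can be expected to separate them; the fixture's 60
  training images are augmented to 600 sheets by the pipeline's own
  augmentation stage before training. The full-width model (224×224,
  C = 512, 2048 fused channels) is exercised structurally and for
  forward passes; training it is a GPU-scale undertaking out of scope
  here.

## Known limitations

- The synthetic benchmark's separability is by construction; results on
  it say nothing quantitative about clinical histopathology.
- ImageNet-pretrained backbone weights are supported but not bundled;
  from-scratch training is the tested path.
- The engine is single-threaded numpy; it favours clarity and exact
  reproducibility over speed and is not suitable for full-width training.
- Bilateral filtering delegates to scikit-image; its sigmas are
  conventional defaults rather than values with any clinical meaning.
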