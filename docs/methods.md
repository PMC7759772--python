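# Methods

`surgmon` implements a two-step monitor for cataract-surgery video sampled
at 1 frame per second.

## Step one: phase/problem classification and the risk level

Two identically shaped convolutional classifiers (an InceptionV3-style
network, input 299×168×3, two softmax outputs) run over every frame. One
recognizes the *important phase* — the span from the start of the
continuous curvilinear capsulorrhexis (CCC) through the end of nuclear
extraction — against all *other* frames; the second recognizes *with
problem* against *without problem* frames.

Each per-second output stream `eval_ij` (j indexes the two output neurons,
i the second) is smoothed with a trailing moving average

    Ave_ij = (1/10) · Σ_{k=i−9..i} eval_kj,   defined for i ≥ 10,

with window 10 s — long enough to suppress single-frame flicker, short
enough to keep the alert latency near real time. The average is undefined
(masked) for the first nine seconds; no padding is invented. The risk
level at second t is the product of the two smoothed streams,

    D_t = PA_t(important) · TA_t(problem) ∈ [0, 1],

using the important-phase probability of the phase network and the
with-problem probability of the problem network — the only pairing under
which D_t rises exactly when a problem occurs during a critical phase.
The estimated problem time is the first second with D_t ≥ threshold
(≥ rather than > so a perfect score still fires at threshold 1.0). A
video's score is its maximum defined D_t; per-video detection is
summarized with an ROC curve, its trapezoid AUC, and an operating
threshold chosen by Youden's J (both the maximum-score aggregation and
the Youden rule are this package's choices; any threshold can also be set
explicitly). Lead times are reported as estimated − annotated seconds,
negative when the detector fires before the annotator.

## Step two: segmentation of cornea, forceps tips and incisional site

An scSE-FC-DenseNet40 (input 256×128×3) emits three per-pixel sigmoid
certainty maps. The layout is an FC-DenseNet U: a 3×3 stem convolution to
48 channels; encoder dense stages of 2/4/8 blocks with 1×1 stride-2
transition convolutions; a 6-block bottleneck; decoder stages of 8/4/2
blocks reached by 3×3 stride-2 transposed convolutions; a 1×1 head to the
three class maps. Each dense block is composite
(batch-norm → ReLU → 3×3 padded convolution) adding a fixed growth of
k = 16 channels — the growth is forced by the printed channel arithmetic
(48→80 over two blocks, 80→144 over four, 144→272 over eight). Each
transition-up carries only the preceding stage's newly produced feature
maps (96/128/64 channels), the FC-DenseNet convention that the transposed
convolution input channel counts force, and concatenates them with the
matching encoder output. A concurrent squeeze-and-excitation (scSE) gate
follows every dense block: a channel gate (global-average squeeze →
reduction-2 bottleneck → sigmoid) and a spatial gate (1×1 convolution to
one sigmoid map), fused elementwise by maximum. The fusion operator and
reduction ratio are configurable (`DenseBlockParams`); max fusion and
reduction 2 are the defaults.

Certainty maps are binarized at 0.5 — the same threshold used for
visualization — and scored with IoU; detection rates
ACC_{IoU≥N} = #{frames with IoU ≥ N} / #frames are tabulated for
N = 0.1 … 0.9. Two conventions the formulas leave open: a frame where
both prediction and truth are empty scores IoU 1.0 (an empty prediction
of an absent object is correct) and is also counted separately, and the
table is reported both over all frames and over frames with nonempty
truth. Objects are 8-connected components (diagonal instrument shafts
stay single objects); each gets its minimum enclosing circle (Welzl's
algorithm on the component's convex hull, radius padded by 0.5 px so
whole pixel squares are enclosed). Gradation overlays map certainty 0 to
blue and 1 to red, alpha-blended over the frame.

## Training recipes

Classification: batch 32, categorical cross-entropy, momentum SGD
(lr 1e-4, momentum 0.9), at most 300 epochs, pixel values normalized to
[0, 1], the `table4` augmentation preset (rotation ≤90°, shifts ≤20%,
shear ≤5°, zoom ≤10%, channel shift ≤100, both flips, random erasing
≤25% of area), and minority-class oversampling: each class is repeated
round(majority/count) times per epoch so per-epoch class counts balance.
Segmentation: batch 16, per-pixel mean squared error on the sigmoid
outputs (the recipe's unusual but deliberate choice), AdaBound (lr 1e-3),
the `table6` preset (geometric transforms only, zoom ≤20%; identical
warps applied to frame and masks, masks re-binarized after
interpolation). Each augmentation transform is applied independently with
probability 0.5 at a magnitude uniform within its limit; order is
geometric → photometric → erasing → normalize, with black border fill.
Whether the channel shift is shared or per-channel is unspecified; it is
per-channel here. Model selection keeps the best-validation-loss state
with early stopping (the recipes state only the 300-epoch cap). The
problem classifier can be trained on all frames (default) or restricted
to important-phase frames (`problem_frame_scope`).

## The numpy network engine

The architectures are realized on a compact NumPy layer engine written
for this package (explicit forward/backward per layer, NHWC layout,
im2col convolutions, momentum-SGD and AdaBound optimizers). Every layer's
backward pass is verified against central finite differences in the test
suite, and the declarative shape-propagation rules (valid convolution:
out = floor((in − k)/stride) + 1; padded convolution preserves dims;
stride-2 transposed convolution doubles them) are checked against the
realized networks' actual intermediate shapes at full size.

Classifier details the architecture table leaves open: Inception branch
widths follow the canonical factorized design (they are forced up to the
stage totals 256/288/288/768/1280/2048); each convolution is
conv → batch-norm → ReLU; the head is 2048 → 1024 → 2 with softmax. The
input is 299×168 per the table (the data description mentions 256×168;
the table's convolution arithmetic is adopted, and the input size is
configurable). No auxiliary heads and no pretrained weights are included.

## The phantom generator

Clinical recordings are private, so the package ships a parametric
phantom: an elliptical "cornea" (jittered center/axes per video) on a
dark background; during the important phase a bright instrument shaft
with a small tip disk orbits the cornea and a short incision arc appears
on the rim; from problem onset a speckled reddening covers ~25% of the
corneal interior. Masks are rendered from the same geometry, so
mask/image agreement is exact by construction. Defaults: 20 videos of
120 s at 1 FPS, important phase spanning fractions 0.35–0.72 of the video
(≈37% of frames, matching the clinical mean of 376 s important vs 642 s
other), half the videos with a problem, onset at fraction 0.4 of the
important phase, pixel noise σ = 0.02. The 120-s duration and 20-video
count are desk-scale choices that keep CPU training in minutes; frame
timestamps are integer seconds from 0; coordinates are row-major,
origin top-left, 0-based.

What the phantom does *not* emulate: photorealistic anatomy, surgical
step diversity beyond the two-class phase scheme, the nine clinical
problem types, occlusions, illumination drift, or annotator noise.
Passing tests therefore demonstrate that the architectures, recipes and
fusion logic are wired correctly and can learn a separable surgical
scene — not clinical-grade accuracy.

## Scaled-down profile and problem sizes

The `small` profile trains the full pipeline on one CPU: classifier
widths ×1/8 at input 151×85 (the largest stride-chain-valid size near
half scale), segmenter growth 8 at input 64×32. Classification training
samples every 2nd frame, segmentation every 4th (segmentation uses
important-phase frames of problem-free videos only, mirroring the
restriction of instrument tracking to clean CCC phases). The published
classification learning rate (1e-4) presumes ImageNet-pretrained
initialization; the small profile trains from scratch and uses 1e-2.
The full augmentation magnitudes are likewise tuned to a six-figure
pretrained-init image count — at desk scale an ablation shows the ±100
per-channel shift alone keeps a freshly initialized network at chance —
so the small profile uses quarter-strength presets
(`table4-small`/`table6-small`: rotation ≤22.5°, shifts ≤5%, shear
≤1.25°, channel shift ≤25; erasing and flips unchanged). All of this is
recorded in the training log like any other override, and the full-size
defaults keep the published recipe verbatim. All random draws
derive from explicit integer seeds; two runs with one seed produce
identical datasets, sampling plans and first-epoch losses.

## Known limitations

- The engine targets clarity and testability, not speed; full-size
  training is impractical on CPU (full-size *inference* and shape audits
  run in seconds).
- AdaBound is implemented in its standard form (element-wise bounds
  closing on final_lr 0.1 with γ = 1e-3) without weight decoupling.
- The phase scheme is strictly two-class; a three-class reading
  (CCC / nuclear extraction / other) appears in the source description
  but conflicts with its own two-neuron output and two-index smoothing
  definition, so the two-stream two-class design is implemented.
- Segmentation classes are independent sigmoids and may overlap; no
  mutual exclusion is imposed.
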