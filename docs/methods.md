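# Methods

## Data model

An exam is three stacked-slice volumes (axial, coronal, sagittal), each an
`L × H × W` real array with its own slice count L (the MRNet on-disk
dialect: one `.npy` stack per exam-view, `H = W = 256` for real data,
64 for the synthetic phantom). A CSV manifest with header
`exam_id,label,axial,coronal,sagittal` carries the binary label
(1 = ACL tear = positive) and file paths. The reader accepts any numeric
dtype and promotes to float, since normalization needs real arithmetic;
variable L is allowed everywhere and reconciled only at batch collation
(pad by edge-replicating the last slice / crop to the central slab,
target = batch median L).

## Synthetic phantom

Each exam is rendered from a latent 64³ scene: an ellipsoidal background
at intensity 0.3, and a 5-voxel-wide band at intensity 1.0 running along
a per-exam jittered diagonal through the mid-slab. A torn (positive) exam
carves the band back to the background level over a 10-voxel gap centred
at a random arc position in [0.35, 0.65], and places a hyperintense
(1.5) blob of band-width radius beside the gap, offset perpendicular to
the band so the centre line inside the gap stays at background — a
geometric stand-in for fiber discontinuity plus local signal abnormality.
Views are slice stacks of the same scene along its three axes (L drawn
uniformly in [16, 24] per view, slices evenly spaced over the central 70%
slab) plus independent Gaussian noise, sd 0.05. Defaults: 30% tear
prevalence (inside the 18–45% range spanned by the reference cohorts),
contrast 0.7 between band and background, i.e. 14 noise sd per voxel —
individually noisy but trivially separable when pooled, which is the
point: the phantom certifies pipeline correctness and module ordering,
not clinical difficulty.

What the phantom deliberately lacks: MR physics (no bias fields, partial
voluming, coil profiles), anatomy (no bones, menisci, or distractor
structures), intensity nonstandardness across exams, and partial tears.
Tests passing on it show the pipeline is wired and trainable, not that
the architecture ranks well on real knees.

## Augmentation

Pipeline per exam: random crop (one shared window per view) →
normalization with the pooled mean/sd of the raw training split (one
scalar pair per dataset; held-out exams reuse training statistics) → one
stochastic op per view. The op is erasing with probability 0.5 or mixup
with probability 0.5 (configurable; remaining mass = no op), at one scale
chosen equiprobably:

* spatial — every slice gets one square block, side = `side × ratio`
  (so the affected area fraction is ratio²; an `area` convention with
  area fraction = ratio is available), position uniform among fully
  inside placements. Erasing zeroes the block; mixup blends it with a
  donor block from another slice of the same view, λ ~ Beta(0.4, 0.4).
* layer — `round(L × ratio)` distinct slices are zeroed outright, or
  blended with random slices of a random *other* view (nearest-neighbour
  resized), λ ~ Beta(0.4, 0.4).

Default ratios: erase 0.5, mixup 0.25, layer 0.25. The side (not area)
convention makes erase 0.75 leave well under half of the image intact,
which matches the qualitative over-augmentation regime the ratios were
tuned against. Labels are never mixed; both ops are class-preserving.
Every stage draws from its own named substream
(`SeedSequence([seed, crc32(stage_name)])`), so toggling one stage never
shifts another's draws, and a single run seed makes the whole pipeline
reproducible.

## Backbone and head

Each slice passes a shared 2-D CNN. `small_cnn` (default): four 3×3
stride-2 conv/ReLU blocks, widths C/4, C/2, C, C with C = 32, giving a
4×4 map on 56–64 px inputs — small enough that the full three-view
comparison trains on one CPU in minutes. `mrnet_alexnet_like` recreates
the AlexNet-features topology at random initialization for 224–256 px
inputs (no pretrained weights are shipped or downloaded). Head: spatial
average pool per slice → element-wise max over slices (depth-invariant;
the most suspicious slice drives the score) → one FC layer → 2-class
softmax.

## Selective group attention

Group module (group size n): layers fold into channels in contiguous
blocks (`L//n` group-layers × `C·n` channels; indivisible L pads by
repeating the last layer, padding dropped on unfold). Directional branch:
1-D average pooling along W and along H, profiles concatenated on the
length axis, a 1×1 convolution over the `C·n` channels (shared across
group-layers and positions), split back, sigmoid, outer product → a
rank-1-per-channel spatial map A′ ∈ (0,1). Global branch: 3×3 conv then
global average pool → one scalar g per group-layer/channel. Fusion of
the branches is multiplicative: mask `M = sigmoid(A′ ⊙ g)`, output
`C_n ⊙ M`. The multiplicative form is the simplest contract in which the
global context gates the directional map; it is isolated in one function
so alternatives are swappable. At zero weights the module reduces to
x/2 exactly (A′ ≡ 0.25, g ≡ 0, sigmoid(0) = 0.5), a useful closed-form
anchor.

Selective module: K = 3 branches with group sizes {1, 2, 4} by default
(n = 1 is pure within-slice attention; larger n trades spatial for
cross-layer context). Branch outputs are summed, pooled over layers and
space to a length-C descriptor (pooling over L keeps branches with
different L//n comparable), passed through a bottleneck FC of width
max(C/r, 8) with r = 4, then K parallel FCs and a softmax *across
branches* per channel. Output = Σ_k z_k ⊙ F_k. The printed form of the
selection step would discard the branch maps (summing reweighted
descriptors only); the implementation follows the selective-kernel
convention, which is what "selecting the best crop group" requires.
Weights are per view — no cross-view sharing.

## Loss and optimization

`L = L_wl + L_fl` with `L_wl = −α_t log p_t`,
`L_fl = −α_t (1−p_t)^γ log p_t`; `p_t` is the probability assigned to the
true class (clamped at 1e−12 before the log), `α_t = α` for tears and
`1−α` otherwise. Default `α = 1 − prevalence(train)` up-weights the rarer
class; `γ = 2` is the canonical focusing value. Optimizer: Adam with L2
weight decay 0.01 and plateau scheduling (×0.8 after 5 stalled epochs on
the tuning loss), following the reference protocol. The default learning
rate is 1e−3: the 1e−5 appropriate for fine-tuning a large pretrained
backbone is far below the useful range for a randomly initialized
desk-scale CNN. Splits are stratified throughout: k-fold plans
(`make_folds`) and the single-split experiment path both keep class
proportions, with a nested 0.8/0.2 train/tune split.

## Fusion

`P_j = (1 − S_aj, 1 − S_cj, 1 − S_sj)`;
`I_j = ‖P_j‖₂ · Σ|P_j| · (1 − cos∠((S_aj,S_cj,S_sj), (1,1,1)))`;
`y = argmin_j I_j`. The cosine distance of an all-zero score vector is
defined as 1 (no direction = maximally distant). One degenerate corner is
handled explicitly: if every view emits *exactly* the same confidence for
a class, that class's score triple is collinear with the ideal direction
and its cosine factor — hence I_j — vanishes regardless of the confidence
level; since this can happen for both classes at once, argmin ties fall
back deterministically to the cosine-free product `P^E · P^M` and then to
the lowest class index. Generic softmax outputs never tie, so the rule is
unchanged on real scores. Single-view mode (external sagittal-only data)
degenerates to argmax of the score vector. For threshold-free ROC
evaluation of the argmin rule a continuous tear score `I_0/(I_0+I_1)` is
exported; this is an artifact convention, not part of the decision rule.

## Metrics

Tear = positive. Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
accuracy = (TP+TN)/total, with errors (not silent zeros) when a class is
absent. AUC is the midrank Mann–Whitney statistic — exact under ties and
identical to trapezoidal ROC integration; the test suite cross-checks it
against both an exhaustive pair-count oracle and scikit-learn. Decision
threshold for the confusion counts is 0.5 on the tear probability.

## Problem sizes and numerical choices

The shipped experiment configuration — 400 exams at 64 px, 15 epochs,
batch 16, crop 56 — is the population on which the module-ordering claim
(full model ≥ plain backbone, fusion within 0.02 of the best view) is
tested; at this size the phantom task saturates (held-out AUC 1.0 for
both variants), so the check certifies "does not hurt" ordering rather
than a strict improvement. All arithmetic is float32 in the network and
float64 in metrics. Tie handling: max-over-layers gradients split equally
among tied slices; argmin/argmax ties resolve to the lowest index.
Degenerate inputs raise (`std = 0` normalization, single-layer spatial
mixup, layer mixup without a donor view, single-class AUC) rather than
returning conventional values.

## Known limitations

No DICOM/NIfTI ingestion (array stacks + CSV manifests only); no
pretrained backbones; no learned fusion; the phantom's separability means
end-to-end tests bound correctness, not real-data performance; the
autodiff engine implements exactly the op set the models use and is not a
general tensor library.
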