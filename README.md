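# sgknee

Multi-view volumetric MRI classification of anterior cruciate ligament
(ACL) tears, built as a tested library plus `sgknee` command line tool.

Radiologists diagnose ACL tears by scanning stacks of knee MRI slices in
three orthogonal planes (axial, coronal, sagittal) for fiber
discontinuities and local signal abnormalities. `sgknee` implements a
classifier pipeline organized the same way:

* **Dual-scale data augmentation (DDA)** — random crop and intensity
  normalization `p' = (p − m)/std`, followed by *erasing* (zeroing a
  region) or *mixup* (convex blending with a donor region, weight
  λ ~ Beta(α, α)) applied either inside slices (spatial scale) or to whole
  slices (layer scale, with mixup donors drawn from the *other* views).
  Labels are never mixed: both operations are class-preserving.
* **Selective group attention (SG)** — the per-slice CNN features
  `X ∈ R^{B×L×C×H×W}` are folded into crop groups of `L/n` group-layers
  with `C·n` channels, forcing cross-layer interactions; each group gets
  coordinate-style directional attention (1-D average pooling along H and
  W, a shared 1×1 convolution, sigmoid, outer product) modulated by a
  global 3×3-conv/average-pool branch. K branches with different group
  sizes n_k are combined by per-channel softmax weights
  `z = Softmax(FC(F''))` — a soft selection of the best cross-layer
  grouping.
* **Weighted + focal loss** — `L = −α_t log p_t − α_t (1−p_t)^γ log p_t`,
  with α defaulting to one minus the tear prevalence of the training
  split and γ = 2, so the rarer tear class and hard examples dominate the
  gradient.
* **Fuzzy-distance fusion** — per-view softmax scores are fused by
  distance to the ideal (all-ones) confidence vector:
  `I_j = ‖1−S_j‖₂ · Σ|1−S_j| · (1 − cos∠(S_j, 1))`, predicted class
  `y = argmin_j I_j`.

Because the real MRNet/KneeMRI cohorts cannot ship with the package, a
**synthetic knee phantom** renders three correlated views of a latent 3-D
scene whose bright diagonal "ligament" band is interrupted (gap plus
hyperintense blob) in positive exams. Every pipeline stage is exercised
end-to-end on this population, and the band geometry is analytic, so the
class signal is traceable in tests.

The neural network layer (`sgknee.autodiff`, `sgknee.nn`) is a compact
numpy reverse-mode autodiff engine with im2col convolutions, gradient-
checked against central finite differences.

## Worked example

```bash
sgknee simulate --n 400 --seed 1 --out-dir runs/data
# wrote 400 exams to runs/data
# positive (ACL-tear) prevalence: 0.3000 (30.0%)

sgknee train --data-dir runs/data --out-dir runs/train --seed 1
sgknee evaluate --checkpoint runs/train/checkpoint.npz \
                --data-dir runs/data --out-dir runs/eval
sgknee fuse --scores runs/eval/scores.csv --out fused.csv
```

`runs/train/metrics.csv` reports one row per view plus the fused row, each
with the confusion counts, accuracy, sensitivity (true-positive rate on
tear exams), specificity (true-negative rate on intact exams) and the
midrank Mann–Whitney AUC on the held-out split. On the default synthetic
population the task is learnable to saturation: all per-view held-out AUCs
and the fused accuracy reach 1.0000 after 15 epochs. `sgknee ablate`
produces the module-efficacy grid (Base / +DDA / +DDA+SG per view, plus
the fused row) as `ablation_table.csv` with per-view ROC exports.

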