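# leafseg

Composite-backbone semantic segmentation for leaf phenotyping, implemented
end-to-end in NumPy (including a small reverse-mode autodiff engine), with a
boundary-aware evaluation suite and a procedural leaf-scene generator.

## The problem

Measuring plant phenotypic traits (leaf area, leaf length) from field imagery
starts with separating the target leaf from soil, weeds and neighbouring
leaves. Encoder–decoder CNNs handle the leaf interior well but blur the leaf
*edge* — exactly the part that drives phenotypic measurements. Convolutional
backbones lack a global receptive field; pure attention backbones need large
datasets and heavy compute. This package implements a composite-backbone
architecture that combines both:

- a **lead backbone** — an Xception-style encoder of five stages L0–L4 built
  from 3×3 separable convolutions with 1×1 residual shortcuts (the L3 stage
  repeats 16 times; the L4 tap is at output stride 16);
- an **assisting backbone** — a CoAtNet-style hybrid of five stages A0–A4: a
  convolution stem, two MBConv (inverted-bottleneck) stages, and two
  relative-attention + FFN stages, repeated 2/4/8/2 times with FFN
  expansion E = 4;
- **composite fusion**: every assisting stage A_i feeds the parallel and all
  lower lead stages L_k (k ≤ i) through 1×1 projection, batch norm, bilinear
  resizing, and a per-channel weight-contribution factor

  ω_i = |γ_i| / Σ_j |γ_j|

  computed from the batch-norm scales γ of the sources meeting at a fusion
  site (Σ ω = 1 per site), followed by element-sum;
- a DeepLab-v3+-style head: ASPP over the L4 tap (1×1 conv, three 3×3 atrous
  convs at rates 6/12/18, image pooling), a decoder that fuses ×4-upsampled
  high-level features with the A1 low-level tap, two dropout layers, and a
  per-pixel softmax;
- **assistant supervision**: the total loss is L = L_comp + λ·L_assist
  (λ = 0.3), where L_assist is cross-entropy through a lightweight head on
  the assisting backbone's low-level path.

Evaluation uses the four standard segmentation metrics, computed from the
pixel confusion matrix p (p_ij = pixels of true class i predicted as j):

    PA   = Σ_i p_ii / Σ_ij p_ij
    MPA  = mean_i p_ii / Σ_j p_ij
    MIoU = mean_i p_ii / (Σ_j p_ij + Σ_j p_ji − p_ii)
    BIoU = |(G_d∩G) ∩ (P_d∩P)| / |(G_d∩G) ∪ (P_d∩P)|

where G_d, P_d are the sets of pixels within d of the truth/prediction
contours — BIoU scores specifically the boundary quality that MIoU
over-states.

Since reference field datasets of this kind are typically not deposited, the
package ships a procedural generator that emulates the five scene conditions
such datasets exhibit — normal leaves, spotted lesions, regional lesions,
occluded blades, uneven illumination — as lobed star-convex silhouettes on
cluttered backdrops, plus the full preprocessing pipeline (median filter,
resize, Labelme polygon rasterisation, rotation/mirror augmentation, 80/20
leakage-safe splitting).

## Worked example

Overfit the desk-scale ("tiny") preset on four synthetic 64×64 scenes for
300 Adam steps and score it on its own training scenes:

```python
from leafseg.train import overfit_tiny

model, log, report = overfit_tiny(seed=1, steps=300)
print(f"steps={len(log.records)}  MIoU={report.MIoU:.3f}  "
      f"BIoU={report.BIoU:.3f}  PA={report.PA:.3f}")
```

which prints

```
steps=300  MIoU=0.979  BIoU=0.871  PA=0.991
```

MIoU near 1 says the leaf body is recovered almost perfectly; BIoU is
noticeably lower because it scores only the band of pixels within d of the
mask contours (d = 2% of the image diagonal by default), where the remaining
errors concentrate — the gap between the two numbers is exactly why the
boundary metric is reported separately.

The same pipeline is scriptable from the shell:

```sh
leafseg generate-data --config cfg.yaml --out data/
leafseg train         --config cfg.yaml --data data/ --out run/
leafseg evaluate      --pred-dir run/preds --truth-dir data/masks
leafseg predict       --model run/model --config cfg.yaml --images data/images --out preds/
leafseg ablate        --config cfg.yaml --data data/ --out ablation/
```

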