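# Methods

## Model

The segmentation network is an encoder–decoder with a composite backbone.
The input is an RGB raster normalised to [0, 1], NCHW; the output is a
per-pixel two-class logit map at input resolution, activated by softmax,
with arg-max (ties to the lower class index, for determinism) giving the
predicted mask.

**Lead backbone (Xception-style).** Five stages L0–L4. L0 is two plain 3×3
convolutions (the first strided); L1–L4 are residual blocks of two 3×3
separable convolutions with a 1×1-convolution shortcut that performs
channel lift and residual transfer. Stage strides are (2, 2, 2, 1, 2), so
the L4 tap sits at output stride 16 — the resolution the ASPP head expects.
Spatial reduction lives in the first separable convolution of a stage.
Every convolution is followed by batch normalisation and ReLU; the exact
Xception channel ladder is configurable, defaulting to
(64, 128, 256, 728, 1024) with 16 L3 repeats. Each stage accepts an
optional additive injection on its input; that is the composite coupling
point.

**Assisting backbone (CoAtNet-style).** Five stages A0–A4 at cumulative
strides (2, 4, 8, 16, 32): a 3×3 convolution stem, two MBConv stages
(1×1 expand → depthwise 3×3 → 1×1 project, pre-norm, residual), and two
attention stages of relative self-attention plus a position-wise FFN with
expansion 4, under channel-wise layer-norm pre-normalisation. Stage repeats
default to (2, 4, 8, 2). Relative attention flattens the h×w×c raster to
(h·w)×c tokens; scores are scaled dot products (1/√head_dim) plus a
translation-indexed bias table of size (2h−1)×(2w−1) per head, built for
the configured input size; rows are softmax-normalised. At off-design
input sizes the bias table is bilinearly resampled and applied as a
constant — the resampled table is not a training path. Downsampling in
attention stages is a stride-2 average pool at stage entry with a 1×1
projection carrying the residual; in MBConv it lives in the depthwise
convolution, with pool + 1×1 on the shortcut. Head size defaults to 32
channels (8 in the tiny preset). A global-pool + FC tail exists solely for
optional standalone pre-training of the trunk.

**Composite fusion.** The default topology is dense higher-to-lower
composition: A_i feeds every lead stage L_k with k ≤ i (15 edges). Each
edge applies a 1×1 projection to the target stage's input channel count,
batch normalisation, and bilinear resizing to the target's spatial size.
Where S sources meet one lead stage, source s's channel c is scaled by
ω_{s,c} = |γ_{s,c}| / Σ_{s'} |γ_{s',c}| — the batch-norm scale magnitudes
of the projections, normalised across sources — and the scaled maps are
element-summed into the stage input. The absolute value makes the factors
convex weights even when a learned γ is negative; Σ_s ω_{s,c} = 1 holds at
every site by construction, at any point in training (the acceptance script
verifies it numerically after 50 optimisation steps). Where the
normalisation direction was ambiguous (per source vs. per channel), we
normalise per channel across the sources of a site: it preserves the
suppression interpretation channel-by-channel and degenerates to ω = 1 for
single-source sites. An alternative "parallel-only" topology (A_i → L_i)
is one config line away; an empty topology disables composition entirely.

**Head.** ASPP over the L4 tap with five branches — 1×1 convolution, three
3×3 atrous convolutions at rates (6, 12, 18), and image pooling (global
average → 1×1 conv → broadcast resize) — concatenated and merged by 1×1
convolution. The image-pooling branch omits batch norm because its 1×1
spatial extent makes batch statistics degenerate. The decoder upsamples
the merged features ×4, concatenates the 1×1-projected low-level tap
(assisting A1 at stride 4; lead L1 when the composite is disabled),
refines with two 3×3 convolutions, applies dropout 0.5 and 0.1 (both
before the final upsampling), upsamples ×4 and projects to class logits.

**Loss.** L = L_comp + λ·L_assist with λ = 0.3 by default (λ = 0 in the
no-assistance ablation). Both terms are two-class softmax cross-entropy,
which for K = 2 coincides with the binary form
Σ_i −(y_i log p_i + (1−y_i) log(1−p_i)) evaluated on the foreground
softmax probability; `cross_entropy` reports the per-image sum and the
per-pixel mean, and optimisation uses the mean for scale stability across
resolutions. Probabilities are clipped to [1e−7, 1−1e−7]. L_assist is the
same loss through a 1×1-conv + upsample head on A1 only — it touches the
main prediction path nowhere, but regularises the assisting trunk's
low-level features.

## Training

Adam (β = (0.9, 0.999), ε = 1e−8) under two regimes:

- **scratch**: lr 5e−4, batch 4, up to 200 epochs;
- **freeze/fine-tune**: phase 1 freezes both backbones (lr 1e−4, batch 8,
  100 epochs), phase 2 unfreezes everything (lr 5e−5, batch 4, 100
  epochs). Freezing removes parameters from optimisation bitwise and puts
  the frozen modules in eval mode so their batch-norm running statistics
  stay fixed as well.

The learning rate follows a reduce-on-plateau rule: when the best epoch
loss has not improved (by more than 1e−6) for 5 consecutive epochs, the
rate halves, bounded below by a floor of 0, and the patience counter
resets; on a flat loss stream the first halving therefore occurs at epoch
patience + 1. Training stops early once the best loss stops moving over a
patience window, or at the epoch/step cap. All shuffling, initialisation
and dropout draw from seeds fanned out of one global seed via
`numpy.random.SeedSequence`, so a run is bit-reproducible.

## Numerical core

The network runs on a reverse-mode autodiff engine in `leafseg.nn`:
float64 tensors, a tape of backward closures, convolution via sliding-
window views with an explicit kernel-position loop in the backward pass,
bilinear resizing as a fixed linear map (half-pixel centres, edge
replication), and batch/layer normalisation composed from primitive ops so
their gradients need no hand derivation. Gradients of every primitive are
tested against central finite differences. Softmax subtracts the row
maximum (a constant shift) before exponentiation. Adam state is kept per
parameter; parameters flagged non-trainable are skipped at step time,
which is how freezing is realised.

Two numerical corner cases worth knowing:

- batch norm on a 1×1-spatial, batch-1 input is degenerate (output equals
  β identically), so gradient-flow checks use batch ≥ 2;
- a bias parameter feeding directly into a normalisation layer is a null
  direction (the normalisation cancels constant channel shifts exactly),
  so "every parameter receives gradient" is asserted per stage, not per
  parameter.

## Synthetic scenes

The generator emulates the five field conditions of leaf-phenotyping
imagery: normal, spotted lesions, regional lesions, occluded blades,
uneven illumination. The silhouette is star-convex with radius
r(θ) = R·(1 + Σ a_n cos(nθ + φ_n)) over 3–7 harmonics, clipped positive —
lobed, leaf-like boundaries are what the boundary-IoU metric needs
exercised; backgrounds carry soil tones and distractor blobs. Scene type
changes appearance only: lesions recolour leaf pixels, illumination
multiplies a linear gradient field (default range 0.55–1.35), and only
occlusion relabels pixels — the occluder removes exactly
round(fraction·|leaf|) leaf pixels nearest a random anchor (default
fraction 0.3) and would raise rather than erase the whole leaf. Masks are
identical across scene types at a fixed seed because silhouette, paint and
scene decoration draw from independent child streams. Default working
resolution is 512×512 (tests use 32–64); a generated corpus defaults to
equal numbers of all five scene types.

What the synthetic data does *not* model: real leaf texture and venation,
camera noise statistics, perspective and scale variation, multiple
overlapping target leaves, and annotation noise. Passing tests therefore
demonstrate that the architecture, losses, metrics and training machinery
are correct and learnable, not that the model reaches field-grade accuracy
— that claim would need real annotated imagery and GPU-scale training.

## Preprocessing and splitting

Median filtering is per-channel over a 3×3 window (reflective edges; the
window size is configurable but must be odd). Images resize bilinearly,
masks by nearest neighbour (labels stay in {0, 1}). Augmentation is the
exact set {identity, rot90, rot180, rot270, horizontal mirror} — arbitrary
angles are excluded so masks stay exact. The 80/20 split shuffles by
*base* sample and keeps all augmented variants of one base together,
preventing a rotated copy of a training image from landing in the test
set; augmentation order (split before/after) therefore does not leak.
Labelme rasterisation samples pixel (r, c) at its centre (c+0.5, r+0.5),
counts boundary-touching centres as inside, and lets later polygons
overwrite earlier ones; it is validated against an independent
point-in-polygon oracle.

## Metrics

PA, MPA and MIoU come from the pooled confusion matrix across a dataset;
BIoU — whose band construction is per-image by definition — is averaged
per image. Classes absent from the truth (or with empty union, for IoU)
are excluded from the per-class means so single-class crops stay scored.
A foreground pixel is contour if any 4-neighbour is background or off the
image; the band is all pixels within Euclidean distance d of the contour
(computed by exact distance transform), with d defaulting to
max(1, round(0.02 × image diagonal)) — the established boundary-IoU
convention — and configurable everywhere it appears. When both
boundary-restricted sets are empty, BIoU is defined as 1. As d grows past
the image diagonal, BIoU reduces exactly to foreground IoU; this limit law
and the symmetry BIoU(G, P) = BIoU(P, G) are verified on random masks.

## Desk-scale presets and problem sizes

The shipped tiny preset uses lead widths (8, 16, 16, 24, 32) with 2 L3
repeats, assisting widths (8, 16, 16, 24, 32) with single-repeat stages
and 8-channel heads, a 32-channel ASPP, and 16-channel low-level
projection. The test suite and acceptance script run this preset on
32–64 px scenes: the overfit demonstration fits four 64×64 scenes for 300
Adam steps at lr 2e−3 (early stopping disabled so the step budget is
spent), and the fusion-normalisation check trains 50 steps at 32×32.
These sizes were chosen as the smallest at which every architectural
mechanism (five strided stages, attention grids, dense fusion, the
decoder's two ×4 upsamplings) is exercised end to end. The equal channel
widths of lead L1 and assisting A1 in both presets let one decoder weight
set serve both low-level sources, which is what makes the
disabled-composite model bitwise identical to the plain lead-backbone
encoder–decoder — the regression baseline for the composite machinery.

## Ablation grid

`ablation_run` trains the toggle grid over {composite, assistant
supervision} and reports MIoU/BIoU per row. The (composite off, assistant
on) cell is undefined by construction — the assistant head lives on the
assisting backbone — so the default grid has three rows; with composite
off the model is exactly the plain lead-backbone encoder–decoder.

## Known limitations

- CPU-only, float64: throughput limits full-size (512×512, full-width)
  training to demonstration purposes.
- The relative-bias resampling path at off-design input sizes is
  inference-only (the resampled table is constant).
- Reducing a model to the plain lead network requires equal lead-L1 and
  assisting-A1 channel widths (true for the shipped presets).
- Binary (leaf/background) labels only; no instance separation of
  overlapping leaves.
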