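# Methods

This note records the model as implemented, the parameters that matter, the
numerical choices made where the design was genuinely open, and what the
synthetic-data results do and do not establish.

## Problem setting

The target regime is tiny-object dense detection: objects around 0.067% of
the frame area, ~12.6 objects per image in clusters, two visually similar
classes, and per-object focus variation. Standard top-down pyramid fusion
struggles here because the texture evidence for a tiny object lives on the
finest maps while its semantics only emerge on coarse maps; the network
below fuses *all* levels once, globally, and then redistributes.

## Architecture

**Backbone.** Standard residual networks (ResNet-50 default; ResNet-101 and
ResNeXt variants are constructible but not benchmarked here). Levels are
named C0 (stem, stride 2) through C4 (stride 32); C5 (stride 64) is a
parameter-free stride-2 subsample of C4. The stem output is taken as C0 —
the finest map with any learned features — and the whole six-level contract
is `ceil(input/stride)` spatial sizes at every level. A reduced-width
`tiny` backbone (widths 16–64, group-normalized) exists purely so training
dynamics can be exercised on one CPU; group statistics rather than batch
statistics keep single-image mini-batches stable.

Making C5 parameter-free is a deliberate deviation from synthesizing it
with a 3×3 convolution on C4: any such convolution adds ≥4.7M parameters
to the real-time build, which is irreconcilable with that build's published
size; the subsample (the classic extra-level trick of pyramid necks)
carries the same information to the fusion stage, where everything is
resized anyway. Because a 1×1 projection commutes with subsampling, C5
shares C4's lateral projection.

**T-FPN.** Configuration per variant: RV fuses C1–C5 on the C2 grid, PV
fuses C0–C4 on the C1 grid — i.e. always the second-finest grid of the set,
balancing resolution against the quadratic token cost of attention. The
fusion-target and coarser levels get bias-free 1×1 laterals to d₁ = 256 and
bilinear resizing; the finest level is reduced by a stride-2 3×3
convolution directly from its raw channels. The stack (5·d₁) is reduced to
d₁ by a 1×1 convolution. The FTM is one pre-norm Transformer block
(LayerNorm → multi-head attention → residual; LayerNorm → MLP → residual);
pre-norm with residuals is assumed because the block's components are
listed but not wired in the source description, and it makes the
zeroed-weights identity property testable. The CFRM applies one shared
bottleneck (reduction 16) to the max- and average-pooled channel
descriptors, sums, and gates with a sigmoid. Expansion is bilinear resize +
per-level bias-free 3×3 convolution.

Attention uses the standard √d_k scaling. Head count defaults to 4 and the
MLP hidden width to d₁; neither affects behavior contracts, and head count
never affects parameter totals (the four projection matrices are
head-independent).

**Head.** FCOS-style: four shared 3×3/GroupNorm tower convolutions per
branch (two in the tiny build), 3×3 prediction convolutions, centerness on
the regression tower, per-level learnable scales, distances decoded with
exp. Scale ranges tie to the stride set as (0, 8·s₁], (8·s₁, 8·s₂], …,
(·, ∞), which reproduces the conventional (0,64], …, (512,∞) ranges for
strides 8–128 and shifts proportionally for the finer RV/PV pyramids —
appropriate when the objects themselves are tiny.

**Loss.** L_total = L_cls + L_reg + L_center with unit weights. Focal loss
(α = 0.25, γ = 2) over all locations normalized by N_pos is the default;
the alternative 256-sample 1:1 positive:negative sampling rule is
implemented behind `use_sampler` but off by default — focal loss exists
precisely to make sampling unnecessary, and the baseline numbers the
package is calibrated against imply the focal convention. With no
positives, normalization falls back to 1 so empty images stay finite.
IoU in the regression loss is clamped at 1e−6 before the logarithm.
At inference, centerness multiplies the classification score for ranking
(the alternative literal reading — scaling box coordinates by centerness —
is geometrically meaningless and was rejected).

## Parameter accounting and reconciliation

Counts are exact and closed-form testable. Conventions that reproduce the
published baseline total of 32,113,484 exactly: ResNet-50 without its
classifier (23,508,032), a bias-free five-level FPN of width 256
(3,866,624), and a GroupNorm-towered two-class head (4,738,828). Bias-free
neck convolutions are therefore the package convention.

For the two T-FPN builds, an enumeration over heads × MLP ratio ×
recalibration reduction × (lateral on the finest level) finds **no**
configuration matching the published totals 33,032,012/33,097,804: the
published PV−RV gap (65,792 = one biased 256×256 layer) cannot arise from
the level-set difference, because the C0-vs-C1 lateral cost always differs
by 49,152 under any symmetric treatment. The shipped default (mlp_ratio 1,
reduction 16, no finest lateral) is the enumeration's closest
configuration: +403,216 (+1.22%) for RV and −39,408 (−0.12%) for PV.
`tddet.tfpn.reconcile_hyperparameters` regenerates the full report.

## Training

Single-image mini-batches, SGD momentum 0.9, weight decay 1e−4, prediction
layers initialized N(0, 0.01²) with the classification bias set for a 0.01
positive prior, 100-step linear warm-up (disabled in unit tests), optional
horizontal flip. The MTM schedule for 16 epochs is (1–8: 667×400 caps, lr
0.0025), (9–12: 1333×800, 0.0025), (13–16: 1333×800, 0.00025); resolutions
are keep-ratio caps, not hard sizes. The pixel-budget fraction of the
schedule, (8·0.2502 + 8)/16 ≈ 0.625, is deterministic arithmetic and is the
hardware-independent content of the training-time-saving claim; wall-clock
savings depend on hardware and are out of scope.

## Synthetic data

The generator emulates: Poisson object counts (mean 12.6), Gaussian
clusters (clustered habit), lognormal per-object areas calibrated to 0.067%
of the frame in expectation, elongated rotated ellipses (aspect 1.4–2.2),
two classes at 50/50 (the dataset's totals are near-equal), and a two-point
blur mixture (sharp σ = 0, defocused σ ∈ [1.5, 3] px on 30% of objects) for
the multi-viewpoint effect; backgrounds are low-frequency green-brown noise
with speckle. The default canvas is 640×480 rather than multi-megapixel:
the *relative* statistics are what matter and full-resolution rasterization
would dominate test time.

It does not emulate: real aphid morphology, occlusion by foliage, lighting
gradients, annotation noise, or inter-class appearance similarity beyond a
color difference. Passing tests on this data therefore establish the
*mechanics* (assignment, losses, decoding, metrics, schedule) and basic
trainability, not field performance.

The `easy` preset (128×128, mean 4 objects, relative area 1.2e−2, no blur,
no overlaps, brighter background) exists for optimization smoke tests. The
acceptance protocol — tiny PV detector, 300 single-image steps at lr 0.01
on 20 easy scenes — reaches AP50 ≈ 0.87 on 10 held-out scenes in about a
minute on one CPU. The coarse-to-fine-vs-low-resolution comparison runs at
a further reduced size (6 train/4 val images at 96 px, 8 short epochs,
3 seeds) chosen so the full suite stays a few minutes.

## Numerical and protocol choices

- Boxes: 0-based continuous corner coordinates internally (width =
  xmax − xmin); the on-disk VOC dialect is 1-based and converted on
  read/write. Image resizing rounds half away from zero; box coordinates
  stay floating point.
- Evaluation is COCO-style (101-point interpolated AP, IoU 0.50:0.05:0.95,
  area splits at 32²/96²) — the protocol implied by reporting APs/APm.
  mRecall, which has no published definition, is the mean over classes of
  maximum recall at IoU 0.5 with ≤100 detections per image. "True
  negatives" are undefined for detection and never computed.
- Efficiency indices divide AP50 *as a fraction* by seconds (the convention
  that reproduces the published worked examples) and round to two decimals.
- NMS: class-wise greedy at IoU 0.5, score threshold 0.025, 100 detections
  per image — conventional defaults, configurable.
- The autodiff engine is float32; max-reductions split gradients evenly
  across ties; probabilities are clamped at 1e−7 inside log terms.

## Known limitations

- CPU-scale only: the full-width RV/PV builds are constructible and
  countable, but training them here is impractical; training claims are
  exercised via the tiny build.
- The FTM is a single Transformer block; multi-block stacks and windowed
  attention are out of scope by design.
- Grouped-convolution (ResNeXt) forward passes are loop-based and slow;
  those backbones are configuration surface, not a benchmark surface.
- `match_detections` is greedy in score order (the standard protocol), not
  a globally optimal assignment.
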