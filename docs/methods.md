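# Methods

## Scope and model family

`uwdetect` implements an n-scale single-stage anchor-free detector for
benthic invertebrates (sea urchin, starfish, conch, scallop) together with
the three architectural substitutions that define its ablation ladder:

* **C2f_SAConv** — the cross-stage C2f blocks gain switchable atrous
  bottlenecks.  Each bottleneck's first conv becomes a SAConv: a rate-1
  and a rate-3 dilated 3×3 branch share a base kernel `w`, the dilated
  branch adds a trainable increment `Δw` (initialised to zero), and a
  learned spatial switch `S(x) = σ(conv1×1(avgpool5×5(x)))` mixes the two
  convexly, `y = S·conv(x, w, 1) + (1−S)·conv(x, w+Δw, 3)`.  The sigmoid
  on the switch is essential: with unbounded mixing weights the output
  would not be confined to the segment between the branch responses.
* **RFESEConv** — an attention convolution replacing standard convs.  It
  (i) injects global context (`x + conv1×1(GAP(x))`), (ii) reweights
  channels by ESE attention (`σ(conv1×1(GAP(x)))`), (iii) extracts
  receptive-field features with a depthwise k×k conv expanding to C·k²
  channels (BN + ReLU), (iv) computes per-position softmax attention over
  each receptive field from an avg/max-pooled summary through a grouped
  1×1 conv, and (v) rearranges the k² attention-weighted features onto a
  (kH×kW) grid fused by a k×k stride-k convolution.
* **ESPPF** — the pooling pyramid is widened and made shallower: the
  1×1-reduced map is split channel-wise, one half passes two 5×5 max
  pools (receptive fields 5 and 9), the other a 13×13 then a 9×9 pool
  (13 and 21); cv1's output plus the four pooled maps (3·hidden channels,
  versus SPPF's 4·hidden) are fused by a 1×1 conv.  Max pooling is
  inherited from SPPF; composition identities (5∘5 ≡ 9, 13∘9 ≡ 21) are
  exact and tested.

Everything runs on a numpy reverse-mode autodiff core written for this
package (`autograd.py`, `ops.py`): grouped/dilated conv via strided
windows and einsum, max/avg pooling, batch norm, nearest upsampling.
This keeps the whole stack — including training — dependency-light and
deterministic on a single CPU.

## Audit conventions

* **Parameters**: the exact sum of all trainable array sizes.  The box
  head's fixed bin-projection vector is not trainable and is excluded.
* **FLOPs**: 2 × multiply-accumulates of every convolution during one
  forward pass at 1×3×640×640 (`MACs = c_out · c_in/g · k² · H_out·W_out`).
  Normalisation, activations, pooling and upsampling are counted as
  zero-cost, the usual profiler convention for detector complexity
  tables.  Reported to two decimals in millions / GigaFLOPs; raw integers
  are kept in the report.

## Calibrated widths and placements

The reference complexity table this package audits against prints, for
the four variants, 3.00/3.20/3.70/3.57 M parameters and
8.10/9.00/7.30/7.10 GFLOPs.  A detector of this family has many width
and placement degrees of freedom that the printed numbers constrain only
jointly, so the free constants were fixed once by exhaustive analytic
search over parameter/FLOP formulas, and are hard-coded:

* Head hidden widths: box branch 40 at all scales; classification branch
  88/72/88 at strides 8/16/32 (`reg_max = 16`, `nc = 4`).
* C2f_SAConv placement: the backbone C2f blocks at P2–P4 (hidden width
  33c/32) and all four neck C2f blocks (hidden width 13c/16).  The
  stride-32 backbone C2f keeps plain bottlenecks.
* RFESEConv placement: every stride-2 downsampling conv in backbone and
  neck, and all twelve 3×3 head branch convs.  Aggregation group counts:
  2/4/4 for the P2/P3/P4 downsamples, dense at P5, 4 in the neck, 8 in
  the head except the two stride-8 second convs (2); one grouped 3×3
  interaction conv (groups 9) sits on the attention branch of the deepest
  classification conv.  The GAP-side 1×1 convs carry parameters at
  negligible FLOP cost, which is why this substitution adds ~0.50 M
  parameters while removing ~1.70 G FLOPs.
* ESPPF hidden width: 32.  This is pinned by the parameter delta of the
  pyramid swap (−0.13 M against SPPF's 164,608 parameters at 256
  channels).

With these constants the audit reproduces 3.00/3.20/3.70/3.57 M and
8.10/9.00/7.30 G exactly (to the printed two decimals).  The fourth FLOP
cell is structurally out of reach: the whole SPPF block at 20×20/256
channels costs only 0.131 G, so no pyramid replacement can remove the
printed 0.2 G; the audited full model is 7.20 G (−0.10 G from the swap).
The corresponding acceptance assertion is left failing by design and
documents this inconsistency instead of masking it.

## Training harness

Assignment is task-aligned: anchors whose centre lies inside a ground
truth are candidates, ranked by `cls^0.5 · IoU^6`; each ground truth
keeps its top-10, and contested anchors go to the best-aligned ground
truth.  Targets are the normalised alignment score.  Losses: CIoU (box),
binary cross-entropy (classification) and the distribution focal loss
over the 16 regression bins, weighted 7.5/0.5/1.5.  Optimisation: SGD,
learning rate 1e-3, momentum 0.937, weight decay 5e-4 (applied to conv
kernels only), batch size 4.  The loss/assigner hyperparameters beyond
these are the established single-stage defaults, adopted as such.

The smoke-training condition exercised by the acceptance suite is 30
epochs over 16 synthetic 160×160 scenes — small enough for a single CPU
core in about a minute, large enough that all three loss components must
fall for the total to drop.  It demonstrates that gradients flow
correctly through every block; it says nothing about detection quality
on real imagery.

## Synthetic scenes

The generator emulates the structure, not the appearance, of shallow
benthic imagery: four class-distinct shapes (spiny disc, five-armed star,
spiral, ridged fan) on a textured gradient seabed; object sides drawn
from the area bins `<18, 18–36, …, 72–90, >90` px with a configurable
mixture (defaults skew small, matching how such datasets are usually
distributed); wavelength-dependent attenuation with red suppressed most
(retention 0.35/0.75/0.92 raised to a tint-strength power), Gaussian
blur (σ = 1 px) and additive noise (σ = 0.02).  Boxes are recorded
before degradation, so photometric corruption never moves an annotation.
Scenes are pure functions of `(spec, seed)` and bit-reproducible.

What passing tests on these scenes shows: geometry handling, assignment,
losses, decoding and metrics are correct end to end.  What it does not
show: robustness to real water-column optics, occlusion statistics of
wild populations, or transfer of trained weights — the generator's
shapes are far easier to separate than real organisms.

## Numerical choices and edge cases

* Same-padding convention `pad = d·(k−1)/2` for odd k; even kernels are
  rejected.  The stride-k aggregation conv uses pad 0 (exact tiling).
* Max-pool padding value is −inf (so pads never win); avg-pool divides
  by the valid window size, so constant inputs stay constant at borders.
* Softmax subtracts the per-group max before exponentiation.
* AP uses 101-point interpolation of the precision envelope; 0/0
  precision or recall is defined as 0; classes without ground truth are
  excluded from the class mean; mAP@0.5:0.95 averages thresholds
  0.50–0.95 in steps of 0.05.
* Greedy matching resolves ties by confidence order; each ground truth
  matches at most once.
* BCE clamps probabilities to [1e-7, 1−1e-7]; CIoU's trade-off
  coefficient is treated as a constant during backprop, the standard
  stabilisation.
* Batch norm uses batch statistics in training and running statistics
  (momentum 0.03) in evaluation.

## Known limitations

* Desk-scale only: no GPU path, no data augmentation, no EMA, no LR
  schedule; mAP figures from full-scale training are out of scope.
* The numpy conv is im2col-based; at 640×640 a full-model forward costs
  roughly a second, fine for auditing but not for video-rate inference.
* The calibrated widths (40/88/72/88, 33c/32, 13c/16, ESPPF hidden 32)
  are audit-derived constants of this reimplementation, not values
  transcribed from a reference implementation.
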