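# Methods

`onsdnet` implements a multi-task deep network for transorbital ultrasound:
joint segmentation of the optic nerve (ON) and optic nerve sheath (ONS),
direct regression of the optic nerve sheath diameter (ONSD), and a
geometric measurement path that extracts OND/ONSD from the predicted masks
at the clinical reference depth of 3 mm behind the globe.  The final ONSD
is the average of the geometric and regressed estimates.  Because clinical
transorbital data cannot ship with the package, a synthetic phantom
generator provides fully controlled inputs with analytically known masks
and diameters; every claim the test suite makes is made on phantoms.

## Network

**Backbone.** Four convolutional stages at strides 4/8/16/32 with channel
widths `w, 2w, 4w, 8w` (conv → batch-norm → ReLU blocks, He init).  The
width `w` is a first-class configuration knob; `w = 8` is the CPU-scale
setting used throughout the tests, larger widths are the intended setting
for real GPU-scale work.  Inputs are single-channel images in [0, 1] whose
side must be divisible by 32.

**Feature aggregation.** Deeper stages are merged iteratively back into
shallower ones: bilinear upsampling, channel concatenation, and a 3×3
conv-BN-ReLU that restores the stage's channel count.  Output stages keep
their input resolutions, so the aggregated pyramid is a drop-in replacement
for the raw one.

**Task branches and attention.** Each task (segmentation, regression) runs
its own attention branch over the aggregated stages.  At stage ℓ the block
refines the shared features (concatenated with the branch's own features
from stage ℓ−1, average-pooled to match resolution; stage 1 sees only the
shared features) through a 3×3 conv-BN-ReLU, then forms a pre-activation
as the sum of a 1×1 spatial conv and a global-average-pooled channel gate,
and squashes it with a sigmoid.  The resulting mask `M ∈ [0,1]^{C×H×W}`
multiplies the shared features element-wise, `F = M ⊙ Q`.  Forcing all
masks to 1 reduces both branches exactly to the shared features — the
model then degrades to a standard shared multi-task network, which is the
designed worst case.

**Heads.** The segmentation branch is decoded U-Net-style down to full
resolution and emits two *independent* sigmoid channels (ON, ONS).  The
two structures are nested, not mutually exclusive, so a 3-class softmax
would mis-state the geometry; nesting is encouraged by the data rather
than hard-constrained.  The regression branch's deepest features are
concatenated with the average-pooled ON probability map (the segmentation
output acting as a spatial prior), pooled globally, and passed through a
two-layer MLP with a softplus output so the predicted ONSD is non-negative
(the output bias starts the prediction near 5 mm, the middle of the
physiological range).  A second two-layer MLP on the pooled deepest
aggregated features produces the noise levels σ_k = softplus(s_k) ≥ 0 used
by the uncertainty-weighted loss, initialised so σ_k ≈ 1.

The network is built on a compact reverse-mode autodiff engine
(`onsdnet.nn`) written on NumPy: im2col convolutions, fused batch-norm,
bilinear up/down-sampling and SGD with momentum.  Every operation's
gradient is verified against central finite differences in the test suite.

## Losses

Three segmentation components enter the uncertainty-weighted sum, each
evaluated per image and summed over the two channels:

* **Dice loss** `1 − (2|p·g| + ε)/(|p| + |g| + ε)` with ε = 1e-6;
* **binary cross-entropy**, probabilities clipped to (1e-7, 1 − 1e-7);
* **shape-distance loss**: with `D(x)` the unsigned distance of pixel x
  from the reference boundary (normalised by its maximum so the component
  is on the same scale as Dice/CE),

      mean( p · D · [outside beyond 1-px dilation]
            + (1 − p) · D · [inside beyond 1-px erosion] ),

  i.e. predicted mass far outside the reference shape and missing mass
  deep inside it are penalised in proportion to boundary distance.  The
  minimum, 0, is attained exactly at p = g.  A pixel-wise MSE component is
  available through configuration as a fourth term.

The combination is

    L_uncertainty = Σ_k ( σ_k · L_k + log(1 + σ_k) ),

and the full objective `L_total = w1 · L_regression + w2 · L_uncertainty`
with `w1 = w2 = 0.5` and `L_regression` the MSE of the regressed ONSD in mm.

**A degeneracy, and the `kendall` mode.**  The combination above is
monotone increasing in every σ_k whenever L_k ≥ 0 (∂/∂σ_k = L_k +
1/(1+σ_k) > 0), so joint minimisation drives σ_k → 0 — and with it the
gradient σ_k·∂L_k/∂θ of every segmentation component.  In end-to-end
training this silences segmentation learning within roughly a hundred
iterations; we observed validation Dice plateauing below 0.2.  The
configuration therefore offers a well-posed alternative,
`loss_mode="kendall"`: `Σ_k ( exp(−s_k) · L_k + s_k )` with unconstrained
log-variances s_k (from the same MLP, pre-softplus), whose stationary
point s_k = −log L_k exists for every positive L_k.  The verbatim form
remains the package default for the loss *function*; the canonical
tiny-training study (`onsdnet.presets`) trains with the `kendall` mode.

## Geometric measurement

The nerve axis is the principal eigenvector of the ON-mask pixel
coordinates, oriented down-image (posteriorly); the "retina" reference
point is operationalised as the most anterior mask pixel along that axis.
This is robust to the globe being absent from the prediction, unlike
centroid-to-centroid constructions.  The diameter at depth d is the chord
of the mask sampled perpendicular to the axis at quarter-pixel steps with
bilinear interpolation; the chord is the contiguous run of interpolated
values ≥ 0.5 containing the axis point (ties count as inside), with
endpoints refined by linear interpolation of the 0.5 crossing, giving
sub-pixel accuracy.  Runs that terminate only because the sampling line
leaves the image are reported as undefined, as are axes estimated from
fewer than 50 foreground pixels; undefined measurements propagate as
`None` fields with a reason, never as exceptions.

OND is measured on the ON mask, ONSD on the ONS mask, both along the axis
estimated from the ON mask at 3 mm depth.  The fused ONSD is the
unweighted mean of the segmentation-derived and regressed values when both
exist, otherwise whichever is available.

## Phantoms

Each phantom is a piecewise-constant scene — anechoic globe (ellipse
cropped at the top of the frame), hypoechoic nerve band of width OND
inside a sheath band of width ONSD running posteriorly from the globe at a
configurable angle — followed by multiplicative speckle and Gaussian blur.
The speckle field is `1 + scale·(R − 1)` with R unit-mean Rayleigh, so it
has unit mean for every dispersion and reduces to the identity at
`scale = 0`.  Masks are computed analytically from the same geometry;
laterally the bands are half-open intervals, which makes the expected
pixel count across a band equal to its true width and the sub-pixel chord
measurement unbiased.  Pixel conventions: 0-based indices, row-major,
pixel-centre coordinates, isotropic spacing.  The default 0.10 mm/px
spacing is a free calibration parameter, not a measured value.

What the phantoms do *not* emulate: attenuation and shadowing, refraction,
depth-dependent point-spread, curved nerves, annotation noise, and
machine/center heterogeneity.  Tests passing on phantoms therefore
demonstrate the correctness of the pipeline's mechanics (geometry,
losses, optimisation, metrics), not clinical-grade accuracy on real
ultrasound.

## Training protocol and metrics

Training uses SGD with momentum 0.9, initial learning rate 5e-3 decayed by
0.99 every 100 iterations, online augmentation (horizontal flip and
rotation, each with independent probability 0.30, angles uniform on
[−20°, 20°]; bilinear for images, nearest-neighbour for label maps), a
fixed binarization threshold of 0.5 (strict: ties map to background), and
subject-level five-fold splitting (images of one subject never straddle a
fold).  Gradients are norm-clipped at 10 for numerical safety.  Everything
— weight init, data order, augmentation draws — derives from explicit
seeds; a rerun with the same seeds is bit-reproducible.

Metrics: SE = TP/(TP+FN), SP = TN/(TN+FP), F1 = 2TP/(2TP+FP+FN) (each as
percentages); HD95 as the maximum over both directions of the 95th
percentile (linear interpolation) of boundary-to-boundary distances, on
8-connected boundary pixels; AUROC via the rank (Mann–Whitney) statistic,
macro-averaged per image; diameter agreement as MAE, Pearson r and the
two-way random, absolute-agreement, single-measurement ICC (ICC(2,1),
computed through `pingouin`, cross-checked in the tests against the
closed-form two-way ANOVA table).  Undefined values (empty masks,
single-class ground truth, zero variance) are flagged, not silently NaN.

## Problem sizes

The canonical CPU-scale study (`onsdnet.presets`) uses 64 phantoms of
96×96 px at 0.2 mm/px (low speckle 0.05, blur 0.5 px), a width-8 backbone,
30 epochs at batch 8 with the protocol above.  This configuration reaches
validation Dice ≈ 0.93 on the ON channel in about two minutes on one core.
Diameter-recovery checks use 100 noise-free phantoms at the native
256×256 / 0.1 mm/px scale.  These sizes are the package's own choices for
a fully-reproducible desk-scale study; nothing prevents configuring the
full-scale protocol (width 64, 150 epochs, batch 24) on real data.

## Known limitations

* The verbatim uncertainty combination is usable as a static weighting but
  degenerate as a learning objective (see above); conclusions about the
  *benefit* of uncertainty weighting cannot be drawn from the phantom
  study.
* The regression head is trained jointly from scratch; on the tiny study
  its error is dominated by the small data volume, and the fused estimate
  inherits part of it.
* HD95 conventions (boundary connectivity, percentile interpolation)
  follow the choices documented above; other implementations may differ at
  the percent level.
* Only straight nerve bands are generated; measurement at depths where a
  real nerve curves would need a curved-axis model.
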