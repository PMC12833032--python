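"""Multi-task attention network for ON/ONS segmentation and ONSD regression.

Architecture
------------
A shared convolutional backbone (four stages at strides 4/8/16/32, channel
widths w, 2w, 4w, 8w) feeds a Feature Aggregation Block that iteratively
merges deeper stages back into shallower ones (bilinear upsampling,
concatenation, convolution).  Two task branches then run over the aggregated
stages.  At every stage l each branch computes a soft attention mask
M_t^(l) in [0, 1] (sigmoid output) from the shared features — and, for
l >= 2, from the branch's own features at the previous stage — and modulates
the shared features element-wise:

    F_t^(l) = M_t^(l) * Q^(l)

With every mask forced to 1 the branches reduce to the plain shared
features, i.e. the model degrades to a standard shared multi-task network.

The segmentation branch decodes its modulated stages U-Net-style into two
independent sigmoid probability maps (ON and ONS; the nerve is a subset of
the sheath, so the channels are nested rather than mutually exclusive).
The regression branch consumes its deepest modulated stage concatenated
with the average-pooled ON probability map (the segmentation output acts as
a spatial prior) and emits a single non-negative ONSD estimate in mm.  A
small MLP on globally pooled aggregated features produces the softplus-
positive noise levels sigma_k used by the uncertainty-weighted loss.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .nn import (Tensor, Module, Conv2d, BatchNorm2d, Linear, ConvBNReLU,
                 concat, avg_pool2d, upsample_bilinear)

__all__ = ["NetConfig", "ModelOutput", "ONSDNet", "binarize", "modulate"]

TOTAL_STRIDE = 32  # stem /2 then four stages /2 each


@dataclass(frozen=True)
class NetConfig:
    in_channels: int = 1
    width: int = 16                 # stage channels are width * (1, 2, 4, 8)
    attention: bool = True          # False: masks fixed at 1 (shared-only model)
    sigma_components: int = 3       # K of the uncertainty-weighted loss
    reg_bias_init: float = 5.0      # softplus pre-activation: start near 5 mm
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "NetConfig":
        return NetConfig(**d)


@dataclass
class ModelOutput:
    """Per-image network outputs (NumPy, batch dimension removed)."""
    prob_on: np.ndarray             # 2-D in [0, 1]
    prob_ons: np.ndarray            # 2-D in [0, 1]
    onsd_regressed: float           # mm, >= 0
    sigmas: np.ndarray              # (K,) noise levels, >= 0


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Strict threshold: ties at the threshold map to background."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    prob = np.asarray(prob)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map has values outside [0, 1]")
    return prob > threshold


def modulate(shared, mask):
    """Element-wise attention modulation F = M * Q (works on arrays or Tensors)."""
    s_shape = shared.shape if hasattr(shared, "shape") else np.shape(shared)
    m_shape = mask.shape if hasattr(mask, "shape") else np.shape(mask)
    if tuple(s_shape) != tuple(m_shape):
        raise ValueError(f"shape mismatch: shared {s_shape} vs mask {m_shape}")
    if isinstance(shared, Tensor) or isinstance(mask, Tensor):
        s = shared if isinstance(shared, Tensor) else Tensor(shared)
        m = mask if isinstance(mask, Tensor) else Tensor(mask)
        return m * s
    return np.asarray(mask) * np.asarray(shared)


class _Backbone(Module):
    def __init__(self, cfg: NetConfig, rng):
        w = cfg.width
        self.stem = ConvBNReLU(cfg.in_channels, w, stride=2, rng=rng)
        self.stages = [
            [ConvBNReLU(w, w, stride=2, rng=rng), ConvBNReLU(w, w, rng=rng)],
            [ConvBNReLU(w, 2 * w, stride=2, rng=rng), ConvBNReLU(2 * w, 2 * w, rng=rng)],
            [ConvBNReLU(2 * w, 4 * w, stride=2, rng=rng), ConvBNReLU(4 * w, 4 * w, rng=rng)],
            [ConvBNReLU(4 * w, 8 * w, stride=2, rng=rng), ConvBNReLU(8 * w, 8 * w, rng=rng)],
        ]

    def __call__(self, x: Tensor) -> list[Tensor]:
        h = self.stem(x)
        feats = []
        for blocks in self.stages:
            for b in blocks:
                h = b(h)
            feats.append(h)
        return feats


class _Aggregator(Module):
    """Iteratively merge deeper stages into shallower ones (up, concat, conv)."""

    def __init__(self, chans: list[int], rng):
        self.merges = [ConvBNReLU(chans[i] + chans[i + 1], chans[i], rng=rng)
                       for i in range(len(chans) - 1)]

    def __call__(self, feats: list[Tensor]) -> list[Tensor]:
        out = [None] * len(feats)
        out[-1] = feats[-1]
        for i in range(len(feats) - 2, -1, -1):
            up = upsample_bilinear(out[i + 1], feats[i].shape[2:])
            out[i] = self.merges[i](concat([feats[i], up], axis=1))
        return out


class _AttentionBlock(Module):
    """Produce a sigmoid mask in [0, 1] for one stage of one task branch.

    A 3x3 conv (F) refines the concatenated shared + previous-task features;
    a 1x1 spatial conv (H) and a global-average-pooled channel gate (G)
    produce the pre-activation, squashed by a sigmoid.
    """

    def __init__(self, ch: int, prev_ch: int | None, rng):
        in_ch = ch + (prev_ch or 0)
        self.refine = ConvBNReLU(in_ch, ch, kernel=3, rng=rng)   # F
        self.spatial = Conv2d(ch, ch, kernel=1, rng=rng)          # H
        self.channel = Linear(ch, ch, rng=rng)                    # G
        self.expects_prev = prev_ch is not None

    def __call__(self, shared: Tensor, prev: Tensor | None) -> Tensor:
        if self.expects_prev and prev is None:
            raise ValueError("attention block at layer >= 2 requires previous-layer "
                             "task features")
        if not self.expects_prev and prev is not None:
            raise ValueError("attention block at layer 1 takes only shared features")
        x = shared if prev is None else concat([shared, prev], axis=1)
        t = self.refine(x)
        gap = t.mean(axis=(2, 3))                        # (N, C)
        gate = self.channel(gap).reshape(t.shape[0], t.shape[1], 1, 1)
        return (self.spatial(t) + gate).sigmoid()


class _Branch(Module):
    """One task branch: per-stage attention masks modulating shared features."""

    def __init__(self, chans: list[int], rng):
        self.blocks = [
            _AttentionBlock(chans[0], None, rng),
            *[_AttentionBlock(chans[i], chans[i - 1], rng) for i in range(1, len(chans))],
        ]

    def __call__(self, shared: list[Tensor], force_mask_one: bool = False
                 ) -> tuple[list[Tensor], list[Tensor]]:
        feats, masks = [], []
        prev = None
        for blk, s in zip(self.blocks, shared):
            if prev is not None:
                prev = avg_pool2d(prev, 2)   # align to the deeper stage's resolution
            if force_mask_one:
                mask = Tensor(np.ones_like(s.data))
            else:
                mask = blk(s, prev)
            f = modulate(s, mask)
            feats.append(f)
            masks.append(mask)
            prev = f
        return feats, masks


class _SegHead(Module):
    """U-Net-style decoder over the modulated stages -> 2 sigmoid channels."""

    def __init__(self, chans: list[int], rng):
        self.merges = [ConvBNReLU(chans[i] + chans[i + 1], chans[i], rng=rng)
                       for i in range(len(chans) - 1)]
        w = chans[0]
        self.up1 = ConvBNReLU(w, w, rng=rng)     # at stride 2
        self.up2 = ConvBNReLU(w, w, rng=rng)     # at full resolution
        self.out = Conv2d(w, 2, kernel=1, rng=rng)

    def __call__(self, feats: list[Tensor], out_hw: tuple[int, int]) -> Tensor:
        d = feats[-1]
        for i in range(len(feats) - 2, -1, -1):
            up = upsample_bilinear(d, feats[i].shape[2:])
            d = self.merges[i](concat([feats[i], up], axis=1))
        half = (out_hw[0] // 2, out_hw[1] // 2)
        d = self.up1(upsample_bilinear(d, half))
        d = self.up2(upsample_bilinear(d, out_hw))
        return self.out(d).sigmoid()             # (N, 2, H, W)


class _RegHead(Module):
    """Deepest regression-branch features + pooled ON prior -> ONSD (mm)."""

    def __init__(self, deep_ch: int, bias_init: float, rng):
        self.mix = ConvBNReLU(deep_ch + 1, deep_ch, rng=rng)
        self.fc1 = Linear(deep_ch, deep_ch, rng=rng)
        self.fc2 = Linear(deep_ch, 1, rng=rng, bias_init=bias_init)

    def __call__(self, deep: Tensor, prob_on: Tensor) -> Tensor:
        pool = prob_on.shape[-1] // deep.shape[-1]
        prior = avg_pool2d(prob_on, pool)
        h = self.mix(concat([deep, prior], axis=1))
        h = h.mean(axis=(2, 3))
        h = self.fc1(h).relu()
        return self.fc2(h).softplus().reshape(-1)   # (N,)


class _SigmaHead(Module):
    """Two-layer MLP on pooled deepest aggregated features -> noise levels.

    Returns (sigma, raw): sigma = softplus(raw) >= 0 feeds the verbatim
    uncertainty combination; the unconstrained raw scores serve as the
    log-variances of the optional "kendall" mode.
    """

    def __init__(self, deep_ch: int, k: int, rng):
        self.fc1 = Linear(deep_ch, deep_ch, rng=rng)
        # softplus(0.5413) ~= 1: start with unit noise levels
        self.fc2 = Linear(deep_ch, k, rng=rng, bias_init=0.5413)

    def __call__(self, deep: Tensor) -> tuple[Tensor, Tensor]:
        h = deep.mean(axis=(2, 3))
        raw = self.fc2(self.fc1(h).relu())
        return raw.softplus(), raw                        # each (N, K)


class ONSDNet(Module):
    """The full dual-branch model.  See the module docstring."""

    def __init__(self, config: NetConfig | None = None):
        self.config = config or NetConfig()
        rng = np.random.default_rng(self.config.seed)
        w = self.config.width
        chans = [w, 2 * w, 4 * w, 8 * w]
        self.backbone = _Backbone(self.config, rng)
        self.aggregator = _Aggregator(chans, rng)
        self.seg_branch = _Branch(chans, rng)
        self.reg_branch = _Branch(chans, rng)
        self.seg_head = _SegHead(chans, rng)
        self.reg_head = _RegHead(chans[-1], self.config.reg_bias_init, rng)
        self.sigma_head = _SigmaHead(chans[-1], self.config.sigma_components, rng)

    # -- input handling ----------------------------------------------------
    def _to_batch(self, image) -> Tensor:
        if isinstance(image, Tensor):
            x = image
        else:
            arr = np.asarray(image, dtype=float)
            if arr.ndim == 2:
                arr = arr[None, None]
            elif arr.ndim == 3:
                arr = arr[:, None]
            x = Tensor(arr)
        H, W = x.shape[2], x.shape[3]
        if H % TOTAL_STRIDE or W % TOTAL_STRIDE:
            raise ValueError(
                f"input spatial size {(H, W)} must be divisible by the backbone's "
                f"total stride {TOTAL_STRIDE}")
        return x

    # -- spec operations ---------------------------------------------------
    def extract_shared_features(self, image) -> list[Tensor]:
        return self.backbone(self._to_batch(image))

    def aggregate_features(self, feats: list[Tensor]) -> list[Tensor]:
        if len(feats) != len(self.backbone.stages):
            raise ValueError(
                f"expected {len(self.backbone.stages)} stages, got {len(feats)}")
        return self.aggregator(feats)

    def forward_batch(self, x: Tensor, force_mask_one: bool = False) -> dict:
        """Run the whole model on an NCHW Tensor; returns Tensors (training path)."""
        x = self._to_batch(x)
        shared = self.backbone(x)
        for i, s in enumerate(shared):
            if not np.all(np.isfinite(s.data)):
                raise RuntimeError(f"non-finite activations in backbone stage {i + 1}")
        agg = self.aggregator(shared)
        force = force_mask_one or not self.config.attention
        seg_feats, seg_masks = self.seg_branch(agg, force_mask_one=force)
        reg_feats, reg_masks = self.reg_branch(agg, force_mask_one=force)
        probs = self.seg_head(seg_feats, (x.shape[2], x.shape[3]))
        if not np.all(np.isfinite(probs.data)):
            raise RuntimeError("non-finite activations in segmentation head")
        onsd = self.reg_head(reg_feats[-1], _slice_channel(probs, 0))
        sigmas, sigma_raw = self.sigma_head(agg[-1])
        return {
            "probs": probs, "onsd": onsd, "sigmas": sigmas, "sigma_raw": sigma_raw,
            "shared": shared, "aggregated": agg,
            "seg_features": seg_feats, "seg_masks": seg_masks,
            "reg_features": reg_feats, "reg_masks": reg_masks,
        }

    def forward(self, image: np.ndarray) -> ModelOutput:
        """Inference on a single 2-D image (eval-mode batch statistics)."""
        was_training = any(getattr(m, "training", False) for m in self.modules())
        self.set_training(False)
        try:
            out = self.forward_batch(image)
        finally:
            self.set_training(was_training)
        probs = out["probs"].data
        return ModelOutput(
            prob_on=probs[0, 0], prob_ons=probs[0, 1],
            onsd_regressed=float(out["onsd"].data[0]),
            sigmas=out["sigmas"].data[0].copy(),
        )

    __call__ = forward


def _slice_channel(t: Tensor, c: int) -> Tensor:
    """Channel slice keeping the channel axis, with gradient routing."""
    out = Tensor(t.data[:, c:c + 1], _prev=(t,))

    def _bw(g):
        if t.requires_grad:
            gt = np.zeros_like(t.data)
            gt[:, c:c + 1] = g
            t._accum(gt)

    out._backward = _bw
    return out
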