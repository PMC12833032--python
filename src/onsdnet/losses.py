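"""Segmentation losses, the uncertainty-weighted combination, and the total loss.

All loss functions accept either plain NumPy arrays (returning a Python
float) or autodiff :class:`~onsdnet.nn.Tensor` objects (returning a Tensor
so gradients can flow during training).  The uncertainty-weighted sum is

    L_uncertainty = sum_k [ sigma_k * L_k + log(1 + sigma_k) ],

with learnable noise levels sigma_k >= 0, and the total training objective is

    L_total = w1 * L_regression + w2 * L_uncertainty,      w1 = w2 = 0.5.

An optional ``"kendall"`` mode replaces the verbatim combination with the
homoscedastic-uncertainty form ``sum_k [ exp(-s_k) * L_k + s_k ]`` (s_k the
log-variances), whose stationary point s_k = -log L_k is well-posed; the
verbatim form is the default.  See docs/methods.md for the discussion of the
verbatim form's degenerate minimum at sigma = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .nn import Tensor

__all__ = [
    "DICE_EPS", "CE_CLIP", "LossBundle",
    "dice_loss", "cross_entropy_loss", "mse_loss", "shape_distance_loss",
    "uncertainty_loss", "total_loss",
]

DICE_EPS = 1e-6   # Dice smoothing constant
CE_CLIP = 1e-7    # cross-entropy probability clipping


@dataclass
class LossBundle:
    """Component losses L_k with their noise levels and the final weights."""
    components: list[tuple[str, float]]
    sigmas: list[float]
    w1: float
    w2: float
    regression: float
    uncertainty: float
    total: float


def _pair(pred, gt):
    tensor_mode = isinstance(pred, Tensor)
    p = pred if tensor_mode else Tensor(np.asarray(pred, dtype=float))
    g = np.asarray(gt.data if isinstance(gt, Tensor) else gt, dtype=float)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    return p, g, tensor_mode


def _ret(val: Tensor, tensor_mode: bool):
    return val if tensor_mode else float(val.data)


def dice_loss(pred, gt, eps: float = DICE_EPS):
    """1 - (2 |pred .* gt| + eps) / (|pred| + |gt| + eps), soft Dice overlap loss."""
    p, g, tm = _pair(pred, gt)
    inter = (p * g).sum()
    val = 1.0 - (2.0 * inter + eps) / (p.sum() + float(g.sum()) + eps)
    return _ret(val, tm)


def cross_entropy_loss(pred, gt, clip: float = CE_CLIP):
    """Mean binary cross-entropy over pixels; pred clipped to (clip, 1-clip)."""
    p, g, tm = _pair(pred, gt)
    pc = p.clamp(clip, 1.0 - clip)
    val = -(Tensor(g) * pc.log() + Tensor(1.0 - g) * (1.0 - pc).log()).mean()
    return _ret(val, tm)


def mse_loss(pred, gt):
    """Mean squared difference (pixel maps or scalar regression targets)."""
    tm = isinstance(pred, Tensor)
    p = pred if tm else Tensor(np.asarray(pred, dtype=float))
    g = np.asarray(gt.data if isinstance(gt, Tensor) else gt, dtype=float)
    if p.data.size != g.size:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    g = g.reshape(p.data.shape)
    val = ((p - Tensor(g)) ** 2).mean()
    return _ret(val, tm)


def shape_distance_weights(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance-transform penalty maps for :func:`shape_distance_loss`.

    Returns ``(w_out, w_in)``: the boundary-distance map restricted to the
    far outside (beyond a 1-px dilation of gt) and to the deep inside
    (within a 1-px erosion).  Distances are normalised by their maximum so
    the loss magnitude is comparable to Dice/cross-entropy.
    """
    gtb = np.asarray(gt).astype(bool)
    if gtb.sum() == 0:
        raise ValueError("shape_distance_loss requires a non-empty ground truth")
    d_out = ndimage.distance_transform_edt(~gtb)
    d_in = ndimage.distance_transform_edt(gtb)
    absd = np.where(gtb, d_in, d_out)
    absd = absd / max(absd.max(), 1.0)
    struct = np.ones((3, 3), dtype=bool)
    dil = ndimage.binary_dilation(gtb, structure=struct)
    ero = ndimage.binary_erosion(gtb, structure=struct)
    return absd * ~dil, absd * ero


def shape_distance_loss(pred, gt):
    """Boundary-alignment loss: predicted mass far outside the reference
    shape and missing mass deep inside it are penalised in proportion to
    their distance from the reference boundary.

        mean( pred * w_out + (1 - pred) * w_in )

    The minimum, 0, is attained exactly at pred = gt.
    """
    p, g, tm = _pair(pred, gt)
    w_out, w_in = shape_distance_weights(g)
    val = (p * Tensor(w_out) + (1.0 - p) * Tensor(w_in)).mean()
    return _ret(val, tm)


def uncertainty_loss(components, sigmas, mode: str = "paper"):
    """Combine component losses with learnable noise levels.

    mode="paper":   sum_k [ sigma_k * L_k + log(1 + sigma_k) ],  sigma_k >= 0
    mode="kendall": sum_k [ exp(-s_k) * L_k + s_k ]  (s_k = log-variances)
    """
    comp = list(components)
    sig = list(sigmas)
    if len(comp) != len(sig):
        raise ValueError(f"{len(comp)} components but {len(sig)} sigmas")
    tm = any(isinstance(v, Tensor) for v in comp + sig)
    total = Tensor(0.0)
    for L, s in zip(comp, sig):
        Lt = L if isinstance(L, Tensor) else Tensor(float(L))
        st = s if isinstance(s, Tensor) else Tensor(float(s))
        if not np.all(np.isfinite(Lt.data)) or not np.all(np.isfinite(st.data)):
            raise ValueError("loss components and sigmas must be finite")
        if mode == "paper":
            if np.any(st.data < 0):
                raise ValueError(f"sigma must be >= 0 in 'paper' mode, got {st.data}")
            total = total + st * Lt + (st + 1.0).log()
        elif mode == "kendall":
            total = total + (-st).exp() * Lt + st
        else:
            raise ValueError(f"unknown uncertainty mode '{mode}'")
    return _ret(total, tm)


def total_loss(l_regression, l_uncertainty, w1: float = 0.5, w2: float = 0.5):
    """w1 * L_regression + w2 * L_uncertainty (default weights 0.5 each)."""
    if w1 < 0 or w2 < 0:
        raise ValueError(f"weights must be >= 0, got w1={w1}, w2={w2}")
    tm = isinstance(l_regression, Tensor) or isinstance(l_uncertainty, Tensor)
    lr = l_regression if isinstance(l_regression, Tensor) else Tensor(float(l_regression))
    lu = l_uncertainty if isinstance(l_uncertainty, Tensor) else Tensor(float(l_uncertainty))
    if not (np.all(np.isfinite(lr.data)) and np.all(np.isfinite(lu.data))):
        raise ValueError("loss terms must be finite")
    return _ret(lr * w1 + lu * w2, tm)
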