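"""Training protocol and evaluation metrics.

Training follows the reference protocol: online augmentation (horizontal
flip and rotation, each firing independently with probability 0.30, rotation
angles uniform on [-20, 20] degrees), SGD with momentum 0.9, initial
learning rate 5e-3 with a step decay of 0.99 every 100 iterations, a fixed
0.5 binarization threshold, and subject-level five-fold splitting.

Metrics: pixel confusion counts, sensitivity / specificity / F1 (reported
as percentages), the 95th-percentile Hausdorff distance on 8-connected
boundary pixels, rank-based AUROC, and diameter agreement (MAE, Pearson,
and the two-way random absolute-agreement single-measurement ICC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from . import losses as L
from .nn import Tensor, SGD
from .network import ONSDNet, NetConfig, binarize
from .phantom import Phantom

__all__ = [
    "TrainConfig", "MetricsReport", "AgreementReport", "TrainHistory",
    "augment", "lr_at", "split_folds", "train",
    "confusion_counts", "se_sp_f1", "hd95", "auroc", "dice_score",
    "diameter_agreement", "evaluate_segmentation",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol; defaults are the reference settings."""
    epochs: int = 150
    batch_size: int = 24
    lr0: float = 5e-3
    momentum: float = 0.9
    decay_factor: float = 0.99
    decay_every_iters: int = 100
    aug_prob: float = 0.30
    rot_range_deg: tuple[float, float] = (-20.0, 20.0)
    folds: int = 5
    val_fraction: float = 0.2
    loss_mode: str = "paper"        # "paper" | "kendall"
    grad_clip: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.epochs, self.batch_size, self.decay_every_iters, self.folds) <= 0:
            raise ValueError("epochs, batch_size, decay_every_iters, folds must be > 0")
        if self.lr0 <= 0 or self.momentum < 0 or self.decay_factor <= 0:
            raise ValueError("invalid optimiser settings")
        if not (0.0 <= self.aug_prob <= 1.0):
            raise ValueError(f"aug_prob must be in [0, 1], got {self.aug_prob}")
        lo, hi = self.rot_range_deg
        if not np.isclose(lo, -hi):
            raise ValueError(f"rotation range must be symmetric, got {self.rot_range_deg}")


def lr_at(iteration: int, cfg: TrainConfig) -> float:
    """Step-decay schedule: lr0 * decay^floor(iteration / decay_every)."""
    if iteration < 0:
        raise ValueError(f"iteration must be >= 0, got {iteration}")
    return cfg.lr0 * cfg.decay_factor ** (iteration // cfg.decay_every_iters)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(image: np.ndarray, masks: np.ndarray, seed: int,
            aug_prob: float = 0.30,
            rot_range_deg: tuple[float, float] = (-20.0, 20.0)
            ) -> tuple[np.ndarray, np.ndarray]:
    """Random horizontal flip and rotation, each firing with ``aug_prob``.

    The identical geometric transform is applied to the image (bilinear) and
    the label map (nearest-neighbour).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    img = np.asarray(image, dtype=float)
    lab = np.asarray(masks)
    if rng.uniform() < aug_prob:
        img = img[:, ::-1].copy()
        lab = lab[:, ::-1].copy()
    if rng.uniform() < aug_prob:
        angle = float(rng.uniform(*rot_range_deg))
        img = ndimage.rotate(img, angle, reshape=False, order=1,
                             mode="constant", cval=0.0)
        lab = ndimage.rotate(lab, angle, reshape=False, order=0,
                             mode="constant", cval=0)
        img = np.clip(img, 0.0, 1.0)
    return img, lab


# ---------------------------------------------------------------------------
# cross-validation splitting
# ---------------------------------------------------------------------------

def split_folds(subject_ids, n_folds: int = 5, seed: int = 0
                ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Subject-level k-fold split: all images of a subject share a fold.

    Returns (train_indices, test_indices) pairs.  Folds are disjoint and
    cover the dataset exactly once.
    """
    ids = np.asarray(subject_ids)
    subjects = np.unique(ids)
    if len(subjects) < n_folds:
        raise ValueError(f"{len(subjects)} subjects cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    fold_of_subject = {subjects[j]: i % n_folds for i, j in enumerate(order)}
    fold_of_image = np.array([fold_of_subject[s] for s in ids])
    out = []
    for f in range(n_folds):
        test = np.flatnonzero(fold_of_image == f)
        trainv = np.flatnonzero(fold_of_image != f)
        out.append((trainv, test))
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Segmentation metrics; percentages in [0, 100], hd95 in mm (or px)."""
    se: float | None
    sp: float | None
    dice: float | None
    hd95: float | None
    auroc: float | None
    per_image: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class AgreementReport:
    """Diameter agreement: MAE (mm), Pearson r, ICC(2,1); flags for undefined."""
    mae: float
    icc: float | None
    pearson: float | None
    n: int
    reason: str | None = None


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) pixel counts for binary maps."""
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.sum(pred & gt))
    fp = int(np.sum(pred & ~gt))
    tn = int(np.sum(~pred & ~gt))
    fn = int(np.sum(~pred & gt))
    return tp, fp, tn, fn


def se_sp_f1(counts: tuple[int, int, int, int]
             ) -> tuple[float | None, float | None, float | None]:
    """Sensitivity, specificity and F1 as percentages; None when undefined.

    SE = TP/(TP+FN), SP = TN/(TN+FP), F1 = 2TP/(2TP+FP+FN), each x 100.
    """
    tp, fp, tn, fn = counts
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be >= 0")
    se = 100.0 * tp / (tp + fn) if tp + fn > 0 else None
    sp = 100.0 * tn / (tn + fp) if tn + fp > 0 else None
    f1 = 100.0 * 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else None
    return se, sp, f1


def dice_score(pred: np.ndarray, gt: np.ndarray) -> float | None:
    """Dice overlap as a percentage (the F1 of the pixel confusion table)."""
    _, _, f1 = se_sp_f1(confusion_counts(pred, gt))
    return f1


def _boundary(mask: np.ndarray) -> np.ndarray:
    """8-connected boundary: foreground pixels with a background 8-neighbour
    (image border counts as background)."""
    m = np.asarray(mask).astype(bool)
    eroded = ndimage.binary_erosion(m, structure=np.ones((3, 3), bool),
                                    border_value=0)
    return m & ~eroded


def hd95(pred: np.ndarray, gt: np.ndarray, spacing: float = 1.0) -> float | None:
    """95th-percentile Hausdorff distance between mask boundaries.

    Directed distances are pooled per direction, the 95th percentile
    (linear interpolation) taken in each, and the maximum of the two
    returned, scaled by ``spacing``.  None when either mask is empty.
    """
    pb = np.argwhere(_boundary(pred))
    gb = np.argwhere(_boundary(gt))
    if len(pb) == 0 or len(gb) == 0:
        return None
    d_pg = cKDTree(gb).query(pb)[0]
    d_gp = cKDTree(pb).query(gb)[0]
    return float(max(np.percentile(d_pg, 95), np.percentile(d_gp, 95)) * spacing)


def auroc(prob, gt) -> float | None:
    """Rank-based (Mann-Whitney) AUROC as a percentage.

    Accepts a single (prob, gt) pair or equal-length lists of pairs; with
    lists the per-image AUROCs are macro-averaged.  None when a ground
    truth contains a single class.
    """
    from sklearn.metrics import roc_auc_score

    probs = prob if isinstance(prob, (list, tuple)) else [prob]
    gts = gt if isinstance(gt, (list, tuple)) else [gt]
    vals = []
    for p, g in zip(probs, gts):
        g = np.asarray(g).astype(int).ravel()
        if g.min() == g.max():
            return None
        vals.append(roc_auc_score(g, np.asarray(p, dtype=float).ravel()))
    return float(100.0 * np.mean(vals))


def diameter_agreement(pred, truth) -> AgreementReport:
    """MAE, Pearson r and ICC(2,1) between paired diameter lists (mm)."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("pred and truth must be equal-length 1-D sequences")
    if len(p) < 3:
        raise ValueError(f"need >= 3 pairs, got {len(p)}")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(t))):
        raise ValueError("inputs must be finite")
    mae = float(np.mean(np.abs(p - t)))
    if p.std() == 0 or t.std() == 0:
        return AgreementReport(mae=mae, icc=None, pearson=None, n=len(p),
                               reason="zero variance in one measurement set")
    pearson = float(np.corrcoef(p, t)[0, 1])

    import pingouin as pg
    n = len(p)
    df = pd.DataFrame({
        "targets": np.tile(np.arange(n), 2),
        "raters": np.repeat(["pred", "truth"], n),
        "score": np.concatenate([p, t]),
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        icc_tab = pg.intraclass_corr(data=df, targets="targets",
                                     raters="raters", ratings="score")
    # two-way random, absolute agreement, single measurement
    sel = icc_tab["Type"].isin(["ICC(A,1)", "ICC2"])
    icc = float(icc_tab.loc[sel, "ICC"].iloc[0])
    return AgreementReport(mae=mae, icc=icc, pearson=pearson, n=n)


def evaluate_segmentation(pred_probs: list[np.ndarray], gts: list[np.ndarray],
                          spacing: float = 1.0, threshold: float = 0.5
                          ) -> MetricsReport:
    """Per-image metrics on one channel, macro-averaged, plus a per-image table."""
    rows = []
    for i, (p, g) in enumerate(zip(pred_probs, gts)):
        b = binarize(p, threshold)
        se, sp, f1 = se_sp_f1(confusion_counts(b, g))
        rows.append({
            "image": i, "se": se, "sp": sp, "dice": f1,
            "hd95": hd95(b, g, spacing), "auroc": auroc(p, g),
        })
    df = pd.DataFrame(rows)

    def _mean(col):
        vals = df[col].dropna()
        return float(vals.mean()) if len(vals) else None

    return MetricsReport(se=_mean("se"), sp=_mean("sp"), dice=_mean("dice"),
                         hd95=_mean("hd95"), auroc=_mean("auroc"), per_image=df)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)


def _batch_losses(net: ONSDNet, images: np.ndarray, labels: np.ndarray,
                  onsd_true: np.ndarray, cfg: TrainConfig) -> tuple[Tensor, dict]:
    """Forward pass + composite loss on one batch (labels: 0/1/2 maps).

    Each component is the batch mean of the per-image loss, summed over the
    two nested channels (ON, ONS); identical to applying the scalar loss
    functions per image, but vectorised over the batch.
    """
    x = Tensor(images[:, None, :, :])
    out = net.forward_batch(x)
    probs = out["probs"]                       # (N, 2, H, W)
    gt = np.stack([(labels == 2), (labels >= 1)], axis=1).astype(float)

    # soft Dice per (image, channel), then batch mean + channel sum
    inter = (probs * Tensor(gt)).sum(axis=(2, 3))
    denom = probs.sum(axis=(2, 3)) + Tensor(gt.sum(axis=(2, 3)))
    dice_mat = 1.0 - (2.0 * inter + L.DICE_EPS) / (denom + L.DICE_EPS)
    # binary cross-entropy, mean over pixels per (image, channel)
    pc = probs.clamp(L.CE_CLIP, 1.0 - L.CE_CLIP)
    ce_map = -(Tensor(gt) * pc.log() + Tensor(1.0 - gt) * (1.0 - pc).log())
    # boundary-distance penalty maps (constants w.r.t. the network)
    w_out = np.zeros_like(gt)
    w_in = np.zeros_like(gt)
    for i in range(gt.shape[0]):
        for c in range(2):
            if gt[i, c].sum() > 0:
                w_out[i, c], w_in[i, c] = L.shape_distance_weights(gt[i, c])
    sd_map = probs * Tensor(w_out) + (1.0 - probs) * Tensor(w_in)

    comp = {
        "dice": dice_mat.mean(axis=0).sum(),
        "ce": ce_map.mean(axis=(2, 3)).mean(axis=0).sum(),
        "shape": sd_map.mean(axis=(2, 3)).mean(axis=0).sum(),
    }

    # verbatim mode weights by sigma = softplus(raw) >= 0; kendall mode uses
    # the unconstrained raw scores as log-variances
    key = "sigmas" if cfg.loss_mode == "paper" else "sigma_raw"
    sig = out[key].mean(axis=0)                # (K,)
    sigmas = [_vec(sig, k) for k in range(net.config.sigma_components)]
    l_unc = L.uncertainty_loss(list(comp.values()), sigmas, mode=cfg.loss_mode)
    l_reg = L.mse_loss(out["onsd"], onsd_true)
    total = L.total_loss(l_reg, l_unc)
    bundle = L.LossBundle(
        components=[(k, float(v.data)) for k, v in comp.items()],
        sigmas=[float(s.data) for s in sigmas],
        w1=0.5, w2=0.5,
        regression=float(l_reg.data),
        uncertainty=float(l_unc.data),
        total=float(total.data),
    )
    info = {
        "loss": float(total.data),
        "l_reg": float(l_reg.data),
        "l_unc": float(l_unc.data),
        "sigmas": [float(s.data) for s in sigmas],
        "components": {k: float(v.data) for k, v in comp.items()},
        "bundle": bundle,
    }
    return total, info


def _vec(t: Tensor, k: int) -> Tensor:
    out = Tensor(t.data[k], _prev=(t,))

    def _bw(g):
        if t.requires_grad:
            gt = np.zeros_like(t.data)
            gt[k] = g
            t._accum(gt)

    out._backward = _bw
    return out


def train(dataset: list[Phantom], cfg: TrainConfig,
          net_config: NetConfig | None = None,
          net: ONSDNet | None = None) -> tuple[ONSDNet, TrainHistory]:
    """Train the dual-branch model on phantoms with the reference protocol.

    The dataset is split into train / validation parts (``cfg.val_fraction``,
    seeded); history records per-epoch mean training loss and validation
    Dice of the ON channel.  Everything (weight init, data order,
    augmentation) derives from ``cfg.seed`` / ``net_config.seed``.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    cfg.validate()
    if net is None:
        net = ONSDNet(net_config or NetConfig())
    rng = np.random.default_rng(cfg.seed)

    n_val = max(1, int(round(cfg.val_fraction * len(dataset)))) \
        if len(dataset) > 1 else 0
    order = rng.permutation(len(dataset))
    val_idx, train_idx = order[:n_val], order[n_val:]
    train_set = [dataset[i] for i in train_idx]
    val_set = [dataset[i] for i in val_idx]

    opt = SGD(net.parameters(), lr=cfg.lr0, momentum=cfg.momentum)
    history = TrainHistory()
    it = 0
    for epoch in range(cfg.epochs):
        net.set_training(True)
        perm = rng.permutation(len(train_set))
        ep_losses = []
        ep_info = None
        for start in range(0, len(train_set), cfg.batch_size):
            batch = [train_set[i] for i in perm[start:start + cfg.batch_size]]
            imgs, labs, onsds = [], [], []
            for ph in batch:
                aug_seed = int(rng.integers(0, 2 ** 31 - 1))
                img, lab = augment(ph.image, ph.label_map, aug_seed,
                                   aug_prob=cfg.aug_prob,
                                   rot_range_deg=cfg.rot_range_deg)
                imgs.append(img)
                labs.append(lab)
                onsds.append(ph.truth.onsd)
            total, info = _batch_losses(
                net, np.stack(imgs), np.stack(labs), np.array(onsds), cfg)
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, iteration {it}: {info}")
            opt.zero_grad()
            total.backward()
            opt.clip_grad_norm(cfg.grad_clip)
            opt.lr = lr_at(it, cfg)
            opt.step()
            ep_losses.append(info["loss"])
            ep_info = info
            it += 1
        val_dice = _validation_dice(net, val_set)
        history.epochs.append({
            "epoch": epoch,
            "train_loss": float(np.mean(ep_losses)),
            "val_dice_on": val_dice,
            "lr": lr_at(max(it - 1, 0), cfg),
            "sigmas": ep_info["sigmas"] if ep_info else None,
        })
    net.set_training(False)
    return net, history


def _validation_dice(net: ONSDNet, val_set: list[Phantom]) -> float | None:
    if not val_set:
        return None
    net.set_training(False)
    x = np.stack([ph.image for ph in val_set])[:, None]
    out = net.forward_batch(Tensor(x))
    vals = []
    for i, ph in enumerate(val_set):
        d = dice_score(binarize(out["probs"].data[i, 0], 0.5), ph.mask_on)
        if d is not None:
            vals.append(d / 100.0)
    return float(np.mean(vals)) if vals else None
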