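"""Model / Results facade over the training and measurement pipeline.

``OnsdTask`` holds the data and configuration; ``fit()`` trains the
dual-branch network and returns an ``OnsdTaskResults`` carrying the trained
network, the per-epoch history, and evaluation / measurement methods, in
the style of statistical modelling packages (model object -> fit() ->
results object with ``summary()``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import measure_ond_onsd, fuse_onsd, DiameterMeasurement
from .network import ONSDNet, NetConfig, ModelOutput, binarize
from .phantom import Phantom
from .train_eval import (TrainConfig, TrainHistory, train,
                         evaluate_segmentation, diameter_agreement)

__all__ = ["OnsdTask", "OnsdTaskResults"]


class OnsdTask:
    """Joint ON/ONS segmentation + ONSD regression model, fitted to a dataset.

    Parameters
    ----------
    dataset : list of Phantom
        Training images with nested masks and true diameters.
    net_config, train_config : optional
        Architecture and optimisation settings.
    """

    def __init__(self, dataset: list[Phantom],
                 net_config: NetConfig | None = None,
                 train_config: TrainConfig | None = None):
        if not dataset:
            raise ValueError("dataset must be non-empty")
        self.dataset = list(dataset)
        self.net_config = net_config or NetConfig()
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_phantoms(cls, phantoms: list[Phantom], **kwargs) -> "OnsdTask":
        return cls(phantoms, **kwargs)

    def fit(self) -> "OnsdTaskResults":
        net, history = train(self.dataset, self.train_config,
                             net_config=self.net_config)
        return OnsdTaskResults(self, net, history)


class OnsdTaskResults:
    def __init__(self, model: OnsdTask, net: ONSDNet, history: TrainHistory):
        self.model = model
        self.net = net
        self.history = history

    # -- inference ---------------------------------------------------------
    def predict(self, image: np.ndarray) -> ModelOutput:
        return self.net.forward(image)

    def measure(self, image: np.ndarray, spacing_mm: float,
                depth_mm: float = 3.0) -> dict[str, DiameterMeasurement]:
        """Full dual-path measurement: segmentation chord, regression, fusion."""
        out = self.predict(image)
        seg = measure_ond_onsd(binarize(out.prob_on), binarize(out.prob_ons),
                               spacing_mm, depth_mm=depth_mm)
        reg = DiameterMeasurement(None, float(out.onsd_regressed),
                                  source="regression", depth_mm=depth_mm)
        fused = fuse_onsd(seg.onsd_mm, reg.onsd_mm, depth_mm=depth_mm)
        return {"segmentation": seg, "regression": reg, "fused": fused}

    # -- evaluation --------------------------------------------------------
    def evaluate(self, phantoms: list[Phantom], spacing_mm: float | None = None):
        """Segmentation metrics (ON channel) and ONSD agreement on a test set."""
        probs, gts = [], []
        rows = []
        for i, ph in enumerate(phantoms):
            sp = spacing_mm or ph.truth.pixel_spacing
            out = self.predict(ph.image)
            probs.append(out.prob_on)
            gts.append(ph.mask_on)
            m = self.measure(ph.image, sp)
            rows.append({
                "image": i,
                "onsd_true_mm": ph.truth.onsd,
                "ond_true_mm": ph.truth.ond,
                "ond_seg_mm": m["segmentation"].ond_mm,
                "onsd_seg_mm": m["segmentation"].onsd_mm,
                "onsd_reg_mm": m["regression"].onsd_mm,
                "onsd_fused_mm": m["fused"].onsd_mm,
            })
        metrics = evaluate_segmentation(probs, gts)
        return metrics, pd.DataFrame(rows)

    def agreement(self, table: pd.DataFrame, column: str = "onsd_fused_mm"):
        ok = table.dropna(subset=[column, "onsd_true_mm"])
        return diameter_agreement(ok[column].to_numpy(),
                                  ok["onsd_true_mm"].to_numpy())

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        h = self.history.as_frame()
        cfg = self.model.train_config
        lines = [
            "ONSD multi-task model — fit summary",
            "=" * 44,
            f"images: {len(self.model.dataset)}   "
            f"backbone width: {self.model.net_config.width}",
            f"epochs: {cfg.epochs}   batch: {cfg.batch_size}   "
            f"lr0: {cfg.lr0:g} (x{cfg.decay_factor} / {cfg.decay_every_iters} it)",
            f"loss mode: {cfg.loss_mode}   seed: {cfg.seed}",
            "-" * 44,
        ]
        if len(h):
            last = h.iloc[-1]
            lines.append(f"final train loss: {last['train_loss']:.4f}")
            if last.get("val_dice_on") is not None and not pd.isna(last["val_dice_on"]):
                lines.append(f"final validation Dice (ON): {last['val_dice_on']:.3f}")
            if last.get("sigmas") is not None:
                sig = ", ".join(f"{s:.3f}" for s in last["sigmas"])
                label = ("noise levels sigma_k" if cfg.loss_mode == "paper"
                         else "log-variances s_k")
                lines.append(f"{label}: [{sig}]")
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training-loss and validation-Dice curves (matplotlib)."""
        import matplotlib.pyplot as plt

        h = self.history.as_frame()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(h["epoch"], h["train_loss"], label="train loss")
        if h["val_dice_on"].notna().any():
            ax2 = ax.twinx()
            ax2.plot(h["epoch"], h["val_dice_on"], color="C1", label="val Dice (ON)")
            ax2.set_ylabel("validation Dice (ON)")
        ax.set_xlabel("epoch")
        ax.set_ylabel("training loss")
        return ax
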