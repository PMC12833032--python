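"""Image / mask / checkpoint / configuration I/O.

Images are 8-bit grayscale PNGs scaled to [0, 1]; RGB inputs are converted
through the standard luminance weights.  Masks travel as 8-bit label PNGs
(0 = background, 1 = sheath-only, 2 = nerve; the nerve is a subset of the
sheath, reconstructed as ``label >= 1``).  Probability maps are written as
16-bit PNGs (quantisation step 1/65535).  Checkpoints are NumPy ``.npz``
archives of the parameter arrays with the network configuration embedded
as JSON.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import yaml
from PIL import Image

from .network import ONSDNet, NetConfig

__all__ = [
    "load_image", "save_image", "load_masks", "save_masks",
    "save_prob_map", "load_prob_map",
    "save_checkpoint", "load_checkpoint", "load_run_config",
]

log = logging.getLogger("onsdnet")


def load_image(path, size: tuple[int, int] | None = None) -> np.ndarray:
    """Load a grayscale image scaled to [0, 1]; optional bilinear resize.

    RGB inputs are converted via luminance (0.299 R + 0.587 G + 0.114 B).
    """
    img = Image.open(path)
    if img.mode not in ("L", "I;16", "I"):
        if img.mode in ("RGB", "RGBA", "P"):
            log.info("converting %s from %s to grayscale via luminance", path, img.mode)
            img = img.convert("L")
        else:
            raise ValueError(f"unsupported image mode '{img.mode}' for {path}")
    if size is not None and img.size != (size[1], size[0]):
        log.info("resizing %s from %s to %s", path, img.size[::-1], size)
        img = img.resize((size[1], size[0]), Image.BILINEAR)
    arr = np.asarray(img, dtype=float)
    scale = 65535.0 if arr.max() > 255 else 255.0
    return np.clip(arr / scale, 0.0, 1.0)


def save_image(path, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(path)


def load_masks(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a label PNG with values {0, 1, 2} -> nested (mask_on, mask_ons)."""
    lab = np.asarray(Image.open(path))
    if lab.ndim != 2:
        raise ValueError(f"label image {path} must be single-channel")
    bad = sorted(int(v) for v in set(np.unique(lab)) - {0, 1, 2})
    if bad:
        raise ValueError(f"label image {path} has unknown values {bad}; "
                         "expected 0 (background), 1 (sheath-only), 2 (nerve)")
    return lab == 2, lab >= 1


def save_masks(path, mask_on: np.ndarray, mask_ons: np.ndarray) -> None:
    lab = np.zeros(np.asarray(mask_on).shape, dtype=np.uint8)
    lab[np.asarray(mask_ons).astype(bool)] = 1
    lab[np.asarray(mask_on).astype(bool)] = 2
    Image.fromarray(lab, mode="L").save(path)


def save_prob_map(path, prob: np.ndarray) -> None:
    """16-bit PNG probability map (quantisation 1/65535)."""
    arr = np.clip(np.asarray(prob, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(arr * 65535).astype(np.uint16)).save(path)


def load_prob_map(path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=float) / 65535.0


def save_checkpoint(path, net: ONSDNet, extra: dict | None = None) -> None:
    """Parameter arrays + embedded JSON config (and optional metadata)."""
    meta = {"config": net.config.to_dict(), "extra": extra or {}}
    state = net.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[ONSDNet, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    net = ONSDNet(NetConfig.from_dict(meta["config"]))
    net.load_state_dict(state)
    net.set_training(False)
    return net, meta.get("extra", {})


def load_run_config(path) -> dict:
    """YAML run configuration as a plain dict."""
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"run config {path} must be a YAML mapping")
    return cfg
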