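"""Synthetic transorbital-ultrasound phantoms with exact ground-truth geometry.

Each phantom emulates the salient structures of a B-mode transorbital scan:
an anechoic globe (ellipse, cropped at the top of the frame), a hypoechoic
optic-nerve band of width OND running posteriorly from the globe inside a
wider sheath band of width ONSD, multiplicative speckle, and Gaussian blur.
Masks and diameters are known analytically, so the phantoms serve as a
fully-controlled stand-in for clinical data when exercising the
segmentation network and the diameter-measurement pipeline.

Conventions: 0-based pixel indices, row-major, pixel-centre coordinates,
isotropic pixel spacing in mm/pixel.  Angles are degrees from the image
vertical (a 0 deg nerve runs straight down the image).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomParams", "Phantom", "generate_phantom", "generate_dataset",
    "speckle_noise", "NerveAxisTruth",
]


@dataclass(frozen=True)
class NerveAxisTruth:
    """Ground-truth nerve axis: globe/nerve interface point and unit direction."""
    interface: tuple[float, float]   # (row, col), pixels
    direction: tuple[float, float]   # unit (drow, dcol), points away from the globe


@dataclass(frozen=True)
class PhantomParams:
    image_size: tuple[int, int] = (256, 256)
    pixel_spacing: float = 0.10            # mm per pixel, isotropic
    globe_center: tuple[float, float] = (50.0, 128.0)   # pixels (row, col)
    globe_radii: tuple[float, float] = (8.0, 10.0)      # mm semi-axes (row, col)
    ond: float = 3.0                       # optic nerve diameter, mm
    onsd: float = 5.5                      # optic nerve sheath diameter, mm
    nerve_angle: float = 0.0               # degrees from image-vertical
    nerve_length: float = 10.0             # mm
    intensity_levels: dict = field(default_factory=lambda: {
        "background": 0.60, "globe": 0.05, "nerve": 0.15, "sheath": 0.40})
    speckle_scale: float = 0.15            # dispersion of the multiplicative field
    blur_sigma: float = 1.0                # Gaussian blur, pixels

    def validate(self) -> None:
        if not (self.onsd > self.ond > 0):
            raise ValueError(
                f"require onsd > ond > 0, got ond={self.ond}, onsd={self.onsd}")
        if self.pixel_spacing <= 0:
            raise ValueError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")
        for name, v in self.intensity_levels.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"intensity level '{name}'={v} outside [0, 1]")
        if self.speckle_scale < 0:
            raise ValueError(f"speckle_scale must be >= 0, got {self.speckle_scale}")
        if self.blur_sigma < 0:
            raise ValueError(f"blur_sigma must be >= 0, got {self.blur_sigma}")
        # nerve/sheath band must stay inside the frame over its full length
        H, W = self.image_size
        iface = np.array(self.axis_truth().interface)
        d = np.array(self.axis_truth().direction)
        perp = np.array([-d[1], d[0]])
        half = 0.5 * self.onsd / self.pixel_spacing
        length = self.nerve_length / self.pixel_spacing
        for u in (0.0, length):
            for s in (-half, half):
                p = iface + u * d + s * perp
                if not (0 <= p[0] < H and 0 <= p[1] < W):
                    raise ValueError(
                        f"nerve band corner {tuple(np.round(p, 1))} outside "
                        f"image bounds {self.image_size}")

    def axis_truth(self) -> NerveAxisTruth:
        theta = np.deg2rad(self.nerve_angle)
        d = np.array([np.cos(theta), np.sin(theta)])   # (drow, dcol), down-image
        a = self.globe_radii[0] / self.pixel_spacing   # row semi-axis, px
        b = self.globe_radii[1] / self.pixel_spacing
        t = 1.0 / np.sqrt((d[0] / a) ** 2 + (d[1] / b) ** 2)
        iface = np.array(self.globe_center) + t * d
        return NerveAxisTruth(interface=(float(iface[0]), float(iface[1])),
                              direction=(float(d[0]), float(d[1])))


@dataclass(frozen=True)
class Phantom:
    image: np.ndarray       # 2-D float in [0, 1]
    mask_on: np.ndarray     # 2-D bool
    mask_ons: np.ndarray    # 2-D bool, superset of mask_on
    truth: PhantomParams
    axis_truth: NerveAxisTruth

    @property
    def label_map(self) -> np.ndarray:
        """8-bit label image: 0=background, 1=sheath-only, 2=nerve."""
        lab = np.zeros(self.image.shape, dtype=np.uint8)
        lab[self.mask_ons] = 1
        lab[self.mask_on] = 2
        return lab


def speckle_noise(image: np.ndarray, scale: float, seed: int) -> np.ndarray:
    """Multiplicative unit-mean Rayleigh-derived speckle, clipped to [0, 1].

    The noise field is ``1 + scale * (R - 1)`` with R unit-mean Rayleigh, so
    its expectation is 1 for any ``scale`` and ``scale=0`` is the identity.
    """
    if scale < 0:
        raise ValueError(f"speckle scale must be >= 0, got {scale}")
    image = np.asarray(image, dtype=float)
    if scale == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    r = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=image.shape)  # E[r] = 1
    return np.clip(image * (1.0 + scale * (r - 1.0)), 0.0, 1.0)


def _band_masks(params: PhantomParams):
    H, W = params.image_size
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    ax = params.axis_truth()
    iface = np.array(ax.interface)
    d = np.array(ax.direction)
    perp = np.array([-d[1], d[0]])
    u = (rows - iface[0]) * d[0] + (cols - iface[1]) * d[1]      # along-axis, px
    v = (rows - iface[0]) * perp[0] + (cols - iface[1]) * perp[1]
    length = params.nerve_length / params.pixel_spacing
    sp = params.pixel_spacing
    in_len = (u >= 0) & (u <= length)
    gc = np.array(params.globe_center)
    a = params.globe_radii[0] / sp
    b = params.globe_radii[1] / sp
    globe = ((rows - gc[0]) / a) ** 2 + ((cols - gc[1]) / b) ** 2 <= 1.0
    # half-open lateral interval: a band of width d covers on average exactly
    # d/spacing pixel centres, so sub-pixel chord measurement is unbiased
    half_on = 0.5 * params.ond / sp
    half_ons = 0.5 * params.onsd / sp
    mask_on = in_len & (v >= -half_on) & (v < half_on) & ~globe
    mask_ons = in_len & (v >= -half_ons) & (v < half_ons) & ~globe
    return mask_on, mask_ons, globe


def generate_phantom(params: PhantomParams, seed: int) -> Phantom:
    """Render one phantom: piecewise-constant geometry -> speckle -> blur."""
    params.validate()
    mask_on, mask_ons, globe = _band_masks(params)
    lv = params.intensity_levels
    img = np.full(params.image_size, lv["background"], dtype=float)
    img[mask_ons] = lv["sheath"]
    img[mask_on] = lv["nerve"]
    img[globe] = lv["globe"]
    img = speckle_noise(img, params.speckle_scale, seed)
    if params.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, params.blur_sigma)
    img = np.clip(img, 0.0, 1.0)
    return Phantom(image=img, mask_on=mask_on, mask_ons=mask_ons,
                   truth=params, axis_truth=params.axis_truth())


_RANGE_FIELDS = {
    "pixel_spacing", "ond", "onsd", "nerve_angle", "nerve_length",
    "speckle_scale", "blur_sigma",
}


def generate_dataset(n: int, ranges: dict[str, tuple[float, float]],
                     seed: int, base: PhantomParams | None = None) -> list[Phantom]:
    """Draw ``n`` phantoms with scalar parameters uniform within ``ranges``.

    Per-item render seeds are derived from the master seed, so the whole
    dataset is reproducible from ``(n, ranges, seed, base)``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    for k, (lo, hi) in ranges.items():
        if k not in _RANGE_FIELDS:
            raise ValueError(f"unknown range field '{k}'; allowed: {sorted(_RANGE_FIELDS)}")
        if hi < lo:
            raise ValueError(f"range for '{k}' has max < min: {(lo, hi)}")
    base = base or PhantomParams()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        for _attempt in range(100):
            draw = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
            p = replace(base, **draw)
            if p.onsd > p.ond:
                break
        else:
            raise ValueError("ranges cannot satisfy onsd > ond")
        item_seed = int(rng.integers(0, 2 ** 31 - 1))
        out.append(generate_phantom(p, seed=item_seed))
    return out


def params_for_size(image_size: int, pixel_spacing: float,
                    **overrides) -> PhantomParams:
    """Scale the default scene geometry to a different frame size/spacing.

    Keeps the globe and nerve proportions of the default 256 px / 0.10 mm
    scene so that small frames used for CPU-scale training remain valid.
    """
    scale_px = image_size / 256.0
    fov_scale = (image_size * pixel_spacing) / (256 * 0.10)
    p = PhantomParams(
        image_size=(image_size, image_size),
        pixel_spacing=pixel_spacing,
        globe_center=(50.0 * scale_px, 128.0 * scale_px),
        globe_radii=(8.0 * fov_scale, 10.0 * fov_scale),
        nerve_length=10.0 * fov_scale,
    )
    return replace(p, **overrides) if overrides else p
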