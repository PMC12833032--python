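"""Geometric OND/ONSD measurement from masks and fusion with the regressor.

The clinical convention measures the optic nerve sheath diameter 3 mm behind
the globe.  Here the nerve axis is estimated from the optic-nerve mask by
principal-component analysis, the "retina" reference point is operationalised
as the most anterior mask pixel along that axis, and the diameter is the
chord of the mask sampled perpendicular to the axis at the requested depth,
with sub-pixel endpoints obtained by linear interpolation of the 0.5 level
crossing.

Degenerate inputs (too few foreground pixels, a sampling line that misses
the mask) yield *undefined* measurements, reported as ``None`` fields rather
than exceptions, so a batch evaluation never crashes on one bad mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "NerveAxis", "DiameterMeasurement",
    "estimate_nerve_axis", "measure_diameter", "measure_ond_onsd", "fuse_onsd",
]

MIN_AXIS_PIXELS = 50
SAMPLE_STEP = 0.25  # quarter-pixel sampling along the measurement chord


@dataclass(frozen=True)
class NerveAxis:
    interface: tuple[float, float]   # (row, col) pixels: most-anterior ON pixel
    direction: tuple[float, float]   # unit (drow, dcol), posterior (down-image)

    @property
    def angle_deg(self) -> float:
        """Angle from image-vertical, positive toward increasing column."""
        return float(np.degrees(np.arctan2(self.direction[1], self.direction[0])))


@dataclass(frozen=True)
class DiameterMeasurement:
    ond_mm: float | None
    onsd_mm: float | None
    source: str                      # "segmentation" | "regression" | "fused"
    depth_mm: float = 3.0
    reason: str | None = None        # populated when a value is undefined


def estimate_nerve_axis(mask_on: np.ndarray,
                        min_pixels: int = MIN_AXIS_PIXELS) -> NerveAxis | None:
    """Principal axis of the ON mask, oriented down-image; None if too sparse."""
    coords = np.argwhere(np.asarray(mask_on).astype(bool))
    if coords.shape[0] < min_pixels:
        return None
    center = coords.mean(axis=0)
    cov = np.cov((coords - center).T)
    evals, evecs = np.linalg.eigh(cov)
    d = evecs[:, np.argmax(evals)]
    if d[0] < 0 or (d[0] == 0 and d[1] < 0):
        d = -d
    d = d / np.linalg.norm(d)
    proj = coords @ d
    iface = coords[np.argmin(proj)].astype(float)
    return NerveAxis(interface=(float(iface[0]), float(iface[1])),
                     direction=(float(d[0]), float(d[1])))


def measure_diameter(mask: np.ndarray, axis: NerveAxis, depth_mm: float,
                     spacing: float, step: float = SAMPLE_STEP) -> float | None:
    """Chord width (mm) of ``mask`` perpendicular to ``axis`` at ``depth_mm``.

    The binary mask is sampled with bilinear interpolation at quarter-pixel
    steps along the perpendicular through the point ``depth_mm`` posterior to
    the axis interface; the chord is the contiguous run of interpolated
    values >= 0.5 containing that point, its endpoints refined by linear
    interpolation of the 0.5 crossing.  Returns None when the axis point
    falls outside the mask or outside the image.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    if depth_mm <= 0:
        raise ValueError(f"depth_mm must be > 0, got {depth_mm}")
    m = np.asarray(mask).astype(float)
    H, W = m.shape
    iface = np.array(axis.interface)
    d = np.array(axis.direction)
    center = iface + (depth_mm / spacing) * d
    if not (0 <= center[0] <= H - 1 and 0 <= center[1] <= W - 1):
        return None
    perp = np.array([-d[1], d[0]])
    half_extent = float(np.hypot(H, W))
    ts = np.arange(-half_extent, half_extent + step, step)
    pts = center[None, :] + ts[:, None] * perp[None, :]
    vals = ndimage.map_coordinates(m, pts.T, order=1, mode="constant", cval=0.0)
    k0 = int(np.argmin(np.abs(ts)))  # sample at the axis point (t = 0)
    if vals[k0] < 0.5:
        return None

    def _edge(direction: int) -> float | None:
        k = k0
        while 0 <= k + direction < len(ts) and vals[k + direction] >= 0.5:
            k += direction
        if not (0 <= k + direction < len(ts)):
            return None  # run reaches the sampling-window end: off-image
        # a crossing caused by leaving the image is not a real mask edge
        p_out = pts[k + direction]
        if not (0 <= p_out[0] <= H - 1 and 0 <= p_out[1] <= W - 1):
            return None
        v_in, v_out = vals[k], vals[k + direction]
        frac = (v_in - 0.5) / (v_in - v_out)
        return ts[k] + direction * frac * step

    t_hi = _edge(+1)
    t_lo = _edge(-1)
    if t_hi is None or t_lo is None:
        return None
    return float((t_hi - t_lo) * spacing)


def measure_ond_onsd(mask_on: np.ndarray, mask_ons: np.ndarray, spacing: float,
                     depth_mm: float = 3.0) -> DiameterMeasurement:
    """Measure both diameters from nested masks; axis comes from the ON mask."""
    mask_on = np.asarray(mask_on)
    mask_ons = np.asarray(mask_ons)
    if mask_on.shape != mask_ons.shape:
        raise ValueError(f"mask shapes differ: {mask_on.shape} vs {mask_ons.shape}")
    axis = estimate_nerve_axis(mask_on)
    if axis is None:
        return DiameterMeasurement(None, None, source="segmentation",
                                   depth_mm=depth_mm, reason="axis undefined")
    ond = measure_diameter(mask_on, axis, depth_mm, spacing)
    onsd = measure_diameter(mask_ons, axis, depth_mm, spacing)
    return DiameterMeasurement(ond, onsd, source="segmentation", depth_mm=depth_mm)


def fuse_onsd(seg_mm: float | None, reg_mm: float | None,
              depth_mm: float = 3.0) -> DiameterMeasurement:
    """Final ONSD: mean of the segmentation-derived and regressed values when
    both are defined, otherwise whichever is available."""
    if reg_mm is not None and not (np.isfinite(reg_mm) and reg_mm >= 0):
        raise ValueError(f"regressed ONSD must be finite and >= 0, got {reg_mm}")
    if seg_mm is None and reg_mm is None:
        return DiameterMeasurement(None, None, source="fused", depth_mm=depth_mm,
                                   reason="both estimates undefined")
    if seg_mm is None:
        val = float(reg_mm)
    elif reg_mm is None:
        val = float(seg_mm)
    else:
        val = 0.5 * (float(seg_mm) + float(reg_mm))
    return DiameterMeasurement(None, val, source="fused", depth_mm=depth_mm)
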