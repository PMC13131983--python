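"""CARTO-like rendering of the voltage field into four 2D projections.

The clinical display paints bipolar voltage with a rainbow ramp: red at
or below the low-voltage threshold, purple at or above the healthy
threshold, hue interpolated linearly in between.  Views are orthographic
projections (AP, PA, INF, SUP) of the camera-facing hemisphere onto a
square RGB image with black background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv

from ..errors import ConfigurationError, InputError
from .mesh import VIEWS
from .phantom import Phantom

# hue (degrees) of the ramp endpoints: red -> the purple (128, 0, 255)
_HUE_LOW = 0.0
_HUE_HIGH = 60.0 * (4.0 + 128.0 / 255.0)  # ~270.12 deg

BACKGROUND_RGB = (0, 0, 0)


@dataclass(frozen=True)
class ColorScale:
    """Voltage-to-colour ramp with configurable clamp thresholds (mV)."""

    v_low: float = 0.1
    v_high: float = 0.5

    def __post_init__(self):
        if self.v_low >= self.v_high:
            raise ConfigurationError("v_low must be strictly below v_high")

    def fraction(self, voltage) -> np.ndarray:
        """Position on the ramp in [0, 1], clamped at both ends."""
        v = np.asarray(voltage, dtype=float)
        return np.clip((v - self.v_low) / (self.v_high - self.v_low), 0.0, 1.0)

    def rgb(self, voltage) -> np.ndarray:
        """8-bit RGB triple(s) for voltage value(s); monotone hue ramp."""
        v = np.asarray(voltage, dtype=float)
        if np.any(v < 0):
            raise InputError("voltage must be non-negative")
        t = self.fraction(v)
        hue = (_HUE_LOW + t * (_HUE_HIGH - _HUE_LOW)) / 360.0
        hsv = np.stack([hue, np.ones_like(hue), np.ones_like(hue)], axis=-1)
        return np.round(hsv_to_rgb(hsv) * 255.0).astype(np.uint8)

    @property
    def top_rgb(self) -> tuple:
        return tuple(int(c) for c in self.rgb(self.v_high))

    def voltage_estimate(self, rgb_image: np.ndarray) -> np.ndarray:
        """Invert rendered colours back to a ramp voltage (clamped scale)."""
        hsv = rgb_to_hsv(np.asarray(rgb_image, dtype=float) / 255.0)
        t = hsv[..., 0] * 360.0 / _HUE_HIGH
        return self.v_low + np.clip(t, 0.0, 1.0) * (self.v_high - self.v_low)


def voltage_to_rgb(voltage, colormap: ColorScale | None = None) -> tuple:
    """Colour of a single voltage value under the clinical ramp."""
    cs = colormap or ColorScale()
    return tuple(int(c) for c in cs.rgb(float(voltage)))


def render_views(phantom: Phantom, colormap: ColorScale | None = None, size: int = 256) -> np.ndarray:
    """Render the four canonical projections of a phantom.

    Returns a (4, size, size, 3) uint8 stack in AP, PA, INF, SUP order.
    Off-anatomy pixels are black; rendering is deterministic.
    """
    if size < 32:
        raise InputError("image side must be at least 32 pixels")
    cs = colormap or ColorScale()
    mesh = phantom.mesh
    vertex_rgb = cs.rgb(phantom.voltage)  # (n_vertices, 3)
    out = np.zeros((4, size, size, 3), dtype=np.uint8)
    out[...] = np.asarray(BACKGROUND_RGB, dtype=np.uint8)
    for vi, view in enumerate(VIEWS):
        mask, vidx = mesh.pixel_map(view, size)
        out[vi][mask] = vertex_rgb[vidx[mask]]
    return out


def low_voltage_fraction_from_views(
    views: np.ndarray,
    colormap: ColorScale | None = None,
    threshold: float | None = None,
    mesh=None,
) -> float:
    """Low-voltage burden re-estimated from the PA and AP pixels alone.

    Counts anatomy (non-background) pixels whose inverted ramp voltage is
    below the threshold (default: the top of the colour scale).  When the
    shell geometry is supplied, each pixel is weighted by the inverse of
    its surface foreshortening (1/|n . d|, clipped), which turns the
    pixel count into a proper surface-area integral.  Used as an
    independent cross-check that rendering preserves the phantom's
    substrate signal.
    """
    from .mesh import _VIEW_FRAMES

    cs = colormap or ColorScale()
    thr = cs.v_high if threshold is None else threshold
    size = views.shape[1]
    total = 0.0
    low = 0.0
    bg = np.asarray(BACKGROUND_RGB, dtype=np.uint8)
    for vi, view in ((0, "AP"), (1, "PA")):
        img = views[vi]
        anatomy = np.any(img != bg, axis=-1)
        is_low = cs.voltage_estimate(img) < thr - 1e-9
        if mesh is None:
            total += float(anatomy.sum())
            low += float(np.sum(anatomy & is_low))
        else:
            mask, vidx = mesh.pixel_map(view, size)
            sel = mask & anatomy
            d = _VIEW_FRAMES[view][0]
            cos = np.abs(mesh.normals[vidx[sel]] @ d)
            w = 1.0 / np.maximum(cos, 0.15)
            total += float(w.sum())
            low += float((w * is_low[sel]).sum())
    return low / max(total, 1e-12)
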