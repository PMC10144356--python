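"""Render simulated trials to bright-wire grayscale frames.

The camera convention matches the phantom recordings the tracker expects: the
wire is drawn bright on a dark background (so binarization keeps the wire as
the white class), with optional faint vessel-wall outlines and additive
Gaussian pixel noise.  One frame is produced per wire polyline, so the frame
count always equals the ground-truth trajectory length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

from .tracking import FrameSequence

__all__ = ["RenderConfig", "OutOfBoundsError", "render_frames"]


class OutOfBoundsError(ValueError):
    """A wire polyline exits the frame."""


@dataclass
class RenderConfig:
    frame_shape: tuple = (480, 640)  # (height, width)
    background: int = 30
    wire_intensity: int = 220
    wire_thickness: int = 3          # odd px
    noise_sd: float = 2.0
    min_contrast: int = 50           # required wire/background margin
    draw_vessel: bool = False
    vessel_intensity: int = 70


def _disk(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1), dtype=bool)
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return yy * yy + xx * xx <= radius * radius


def _stamp_polyline(canvas: np.ndarray, poly: np.ndarray):
    pts = np.rint(poly).astype(int)
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(y0, x0, y1, x1)
        canvas[rr, cc] = True
    canvas[pts[-1, 1], pts[-1, 0]] = True


def _vessel_layer(phantom, cfg) -> np.ndarray:
    """Faint lumen-wall outlines (both offsets of each centerline)."""
    layer = np.zeros(cfg.frame_shape, dtype=bool)
    for seg in phantom.segments.values():
        pts = seg.centerline
        d = np.gradient(pts, axis=0)
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        n = np.column_stack([-d[:, 1], d[:, 0]]) / norm
        for side in (-1.0, 1.0):
            wall = pts + side * seg.radius * n
            wall[:, 0] = np.clip(wall[:, 0], 0, cfg.frame_shape[1] - 1)
            wall[:, 1] = np.clip(wall[:, 1], 0, cfg.frame_shape[0] - 1)
            _stamp_polyline(layer, wall)
    return layer


def render_frames(trial, config: RenderConfig | None = None, seed: int = 0,
                  phantom=None) -> FrameSequence:
    """Render one frame per wire polyline of a simulated trial.

    Additive Gaussian pixel noise uses the given seed; the same trial and
    seed produce identical pixel arrays.  Raises :class:`OutOfBoundsError` if
    any wire vertex (with its thickness margin) leaves the frame.
    """
    cfg = config or RenderConfig()
    if cfg.wire_intensity <= cfg.background + cfg.min_contrast:
        raise ValueError(
            f"wire intensity must exceed background + {cfg.min_contrast}"
        )
    h, w = cfg.frame_shape
    margin = cfg.wire_thickness // 2
    rng = np.random.default_rng(seed)
    structure = _disk(cfg.wire_thickness // 2)

    base = np.full((h, w), float(cfg.background))
    if cfg.draw_vessel:
        if phantom is None:
            raise ValueError("draw_vessel=True needs the phantom")
        base[_vessel_layer(phantom, cfg)] = float(cfg.vessel_intensity)

    n = len(trial.wire_polylines)
    frames = np.empty((n, h, w), dtype=np.uint8)
    canvas = np.zeros((h, w), dtype=bool)
    for j, poly in enumerate(trial.wire_polylines):
        if (
            poly[:, 0].min() < margin or poly[:, 0].max() > w - 1 - margin
            or poly[:, 1].min() < margin or poly[:, 1].max() > h - 1 - margin
        ):
            raise OutOfBoundsError(f"wire polyline exits the frame at frame {j}")
        canvas[:] = False
        _stamp_polyline(canvas, poly)
        if margin > 0:
            canvas = ndimage.binary_dilation(canvas, structure=structure)
        img = base.copy()
        img[canvas] = float(cfg.wire_intensity)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
        frames[j] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return FrameSequence(frames=frames, fps=trial.meta.get("fps", 20.0))
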