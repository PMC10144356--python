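"""Frame-by-frame guidewire tip detection and tracking.

The wire appears as a bright curve on a dark background.  Each frame is
binarized with a cut-off threshold (Otsu's inter-class-variance criterion by
default), and the tip is localized as the strongest Shi-Tomasi corner: the
pixel maximizing the smaller eigenvalue of the local gradient structure
tensor.  After the first frame, the search is restricted to a square region
of interest (ROI) around the previous tip; a failed detection doubles the ROI
once and otherwise marks the frame invalid, to be filled by interpolation or
manual fixes.

Conventions: 8-bit grayscale frames, row-major, origin top-left, x = column,
y = row, 0-based indices; times in seconds (t = frame_index / fps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

__all__ = [
    "FrameSequence",
    "WireObservation",
    "TipTrajectory",
    "TrackingConfig",
    "UnrecoverableStartError",
    "binarize_frame",
    "corner_scores",
    "detect_tip",
    "track_sequence",
    "apply_manual_fixes",
    "polyline_from_mask",
]


class UnrecoverableStartError(RuntimeError):
    """First-frame tip detection failed and no seed hint was given."""


@dataclass(eq=False)
class FrameSequence:
    """An ordered stack of 8-bit grayscale frames plus the capture rate."""

    frames: np.ndarray  # (n, h, w) uint8
    fps: float = 20.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:]


@dataclass(eq=False)
class WireObservation:
    """Per-frame wire evidence: the tip, validity, and (optionally) the
    binarized wire mask and an ordered centerline polyline."""

    frame_index: int
    tip: tuple | None
    score: float = 0.0
    valid: bool = True
    tip_source: str = "detected"  # detected | interpolated | manual | simulated
    wire_mask: np.ndarray | None = None
    wire_polyline: np.ndarray | None = None


@dataclass(eq=False)
class TipTrajectory:
    """Ordered tip positions: t strictly increasing, coordinates finite."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) < 1:
            raise ValueError("trajectory needs at least one sample")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")

    @property
    def n(self) -> int:
        return len(self.t)

    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def binarize_frame(frame: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Binarize a grayscale frame: 1 where intensity >= threshold.

    ``threshold=None`` selects the cut-off automatically by maximizing the
    inter-class variance of the frame histogram (Otsu's criterion).  The wire
    is the bright class, so the mask is 1 on the wire.  All-0 and all-1 masks
    are legal outputs.
    """
    frame = np.asarray(frame)
    if threshold is None:
        if frame.min() == frame.max():
            return np.zeros(frame.shape, dtype=bool)
        # Otsu's threshold is the top bin of the dark class: the wire is
        # strictly above it
        return frame > threshold_otsu(frame)
    return frame >= threshold


def corner_scores(image: np.ndarray, window_half_width: int = 2) -> np.ndarray:
    """Shi-Tomasi corner response: the smaller eigenvalue of the gradient
    structure tensor box-summed over a (2w+1)^2 window at every pixel.

    Gradients are central differences (one-sided at the borders); window sums
    treat pixels outside the image as zero.  Scores are >= 0.
    """
    w = int(window_half_width)
    if w < 1:
        raise ValueError("window_half_width must be >= 1")
    image = np.asarray(image, dtype=float)
    if min(image.shape) < 2 * w + 1:
        raise ValueError("image smaller than the scoring window")
    gy, gx = np.gradient(image)
    size = 2 * w + 1
    k = float(size * size)
    sxx = ndimage.uniform_filter(gx * gx, size, mode="constant", cval=0.0) * k
    syy = ndimage.uniform_filter(gy * gy, size, mode="constant", cval=0.0) * k
    sxy = ndimage.uniform_filter(gx * gy, size, mode="constant", cval=0.0) * k
    half_tr = 0.5 * (sxx + syy)
    root = np.sqrt(np.maximum((0.5 * (sxx - syy)) ** 2 + sxy**2, 0.0))
    return np.maximum(half_tr - root, 0.0)


def _roi_bounds(roi, shape):
    if roi is None:
        return 0, 0, shape[1], shape[0]
    x0, y0, x1, y1 = (int(round(v)) for v in roi)
    x0 = max(x0, 0)
    y0 = max(y0, 0)
    x1 = min(x1, shape[1])
    y1 = min(y1, shape[0])
    if x1 <= x0 or y1 <= y0:
        raise ValueError("roi lies outside the frame")
    return x0, y0, x1, y1


def _candidate_corners(frame, roi, score_floor, window_half_width):
    """Local maxima of the corner score inside the ROI, with scores.

    The score raster is computed on a padded sub-image so that interior ROIs
    see exactly the full-frame scores at a fraction of the cost.
    """
    x0, y0, x1, y1 = _roi_bounds(roi, frame.shape)
    pad = window_half_width + 2
    sx0, sy0 = max(x0 - pad, 0), max(y0 - pad, 0)
    sub = frame[sy0 : y1 + pad, sx0 : x1 + pad]
    scores = corner_scores(sub, window_half_width)
    # restrict to the ROI proper
    view = scores[y0 - sy0 : y1 - sy0, x0 - sx0 : x1 - sx0]
    local_max = view == ndimage.maximum_filter(scores, size=3)[
        y0 - sy0 : y1 - sy0, x0 - sx0 : x1 - sx0
    ]
    qualify = local_max & (view >= score_floor) & (view > 0)
    ys, xs = np.nonzero(qualify)
    return xs + x0, ys + y0, view[ys, xs], scores, (sx0, sy0)


def _subpixel_refine(scores, x, y, origin):
    """Quadratic (parabolic) sub-pixel refinement of a score maximum."""
    sx0, sy0 = origin
    iy, ix = y - sy0, x - sx0
    fx, fy = float(x), float(y)
    if 0 < ix < scores.shape[1] - 1:
        left, c, right = scores[iy, ix - 1], scores[iy, ix], scores[iy, ix + 1]
        denom = left - 2 * c + right
        if denom < 0:
            fx += float(np.clip(0.5 * (left - right) / denom, -0.5, 0.5))
    if 0 < iy < scores.shape[0] - 1:
        up, c, down = scores[iy - 1, ix], scores[iy, ix], scores[iy + 1, ix]
        denom = up - 2 * c + down
        if denom < 0:
            fy += float(np.clip(0.5 * (up - down) / denom, -0.5, 0.5))
    return fx, fy


def detect_tip(
    frame: np.ndarray,
    roi=None,
    prev_tip=None,
    seed_hint=None,
    score_floor: float = 0.0,
    window_half_width: int = 2,
    subpixel: bool = False,
):
    """Locate the guidewire tip inside a ROI.

    Returns ``((x, y), score)`` for the highest-scoring qualifying corner, or
    ``None`` when no corner reaches ``score_floor`` (a detection failure to be
    recorded, not an exception).  Ties are broken by smaller y then smaller x;
    with ``seed_hint`` (or ``prev_tip``) the qualifying corner nearest the
    hint wins instead.
    """
    frame = np.asarray(frame)
    hint = seed_hint if seed_hint is not None else prev_tip
    xs, ys, vals, scores, origin = _candidate_corners(
        frame, roi, score_floor, window_half_width
    )
    if len(xs) == 0:
        return None
    if hint is not None:
        hx, hy = float(hint[0]), float(hint[1])
        d2 = (xs - hx) ** 2 + (ys - hy) ** 2
        order = np.lexsort((xs, ys, d2))
    else:
        order = np.lexsort((xs, ys, -vals))
    best = order[0]
    x, y, score = int(xs[best]), int(ys[best]), float(vals[best])
    if subpixel:
        fx, fy = _subpixel_refine(scores, x, y, origin)
        return (fx, fy), score
    return (float(x), float(y)), score


@dataclass
class TrackingConfig:
    roi_size: int = 41           # ROI side length in px, centered on the last tip
    threshold: float | None = None  # binarization cut-off; None = automatic
    window_half_width: int = 2
    score_floor_frac: float = 0.01  # floor = frac * max first-frame score
    subpixel: bool = True
    snap_to_wire_end: bool = True   # refine the corner peak to the wire extremity
    insertion_side: str = "bottom"  # fallback tip/tail disambiguation
    keep_masks: bool = True


def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy * yy + xx * xx <= radius * radius).astype(np.int16)


_ENDPOINT_DISK = _disk_footprint(3)


def _snap_to_wire_end(frame, tip, threshold, radius: int = 5, pullback: float = 1.0):
    """Refine a corner peak to the wire extremity.

    The min-eigenvalue peak of a line termination sits a couple of pixels
    inside the wire.  Among the wire-mask pixels near the peak, the tip is the
    one with the fewest wire neighbors (the free end); the estimate is then
    pulled back along the outward direction by the cap radius.
    """
    x, y = int(round(tip[0])), int(round(tip[1]))
    h, w = frame.shape
    half = radius + 4
    x0, x1 = max(x - half, 0), min(x + half + 1, w)
    y0, y1 = max(y - half, 0), min(y + half + 1, h)
    sub = frame[y0:y1, x0:x1] >= threshold
    if not sub.any():
        return tip
    counts = ndimage.convolve(sub.astype(np.int16), _ENDPOINT_DISK, mode="constant")
    yy, xx = np.nonzero(sub)
    gx, gy = xx + x0, yy + y0
    near = (gx - tip[0]) ** 2 + (gy - tip[1]) ** 2 <= radius * radius
    if not near.any():
        return tip
    cand = np.nonzero(near)[0]
    order = np.lexsort((gx[cand], gy[cand], counts[yy[cand], xx[cand]]))
    best = cand[order[0]]
    ex, ey = float(gx[best]), float(gy[best])
    dx, dy = ex - tip[0], ey - tip[1]
    norm = float(np.hypot(dx, dy))
    if norm > pullback:
        ex -= pullback * dx / norm
        ey -= pullback * dy / norm
    return (ex, ey)


def _select_tip_candidate(frame, roi, score_floor, window_half_width, threshold):
    """Choose the tip among qualifying ROI corners.

    Both the tip end-cap and tight wire bends are strong min-eigenvalue
    corners, and pixel noise can rank a bend above the cap.  The tip is the
    corner sitting at a free end of the wire, so candidates are ranked first
    by the sparsity of binarized wire pixels around them (an end has about
    half the neighborhood of a bend), then by score.
    """
    xs, ys, vals, scores, origin = _candidate_corners(
        frame, roi, score_floor, window_half_width
    )
    if len(xs) == 0:
        return None
    x0, y0, x1, y1 = _roi_bounds(roi, frame.shape)
    pad = 8
    sx0, sy0 = max(x0 - pad, 0), max(y0 - pad, 0)
    sub = frame[sy0 : y1 + pad, sx0 : x1 + pad] >= threshold
    counts = ndimage.convolve(sub.astype(np.int16), _ENDPOINT_DISK, mode="constant")
    wy, wx = np.nonzero(sub)
    endpointness = np.full(len(xs), np.inf)
    if len(wy):
        gx, gy = wx + sx0, wy + sy0
        for i in range(len(xs)):
            near = (gx - xs[i]) ** 2 + (gy - ys[i]) ** 2 <= 25
            if near.any():
                endpointness[i] = counts[wy[near], wx[near]].min()
    if not np.isfinite(endpointness).any():
        return None
    order = np.lexsort((xs, ys, -vals, endpointness))
    best = order[0]
    return (float(xs[best]), float(ys[best])), float(vals[best])


def _border_hint(frame_shape, side):
    h, w = frame_shape
    return {
        "bottom": (w / 2, h - 1),
        "top": (w / 2, 0),
        "left": (0, h / 2),
        "right": (w - 1, h / 2),
    }[side]


def track_sequence(
    frames: FrameSequence,
    config: TrackingConfig | None = None,
    seed_hint=None,
):
    """Track the tip through a frame sequence.

    The first frame is searched whole-frame (seeded by ``seed_hint`` when
    given, else by proximity to the configured insertion-side border).  Each
    later frame is searched in a square ROI centered on the previous tip; on
    failure the ROI side is doubled once, then the frame is marked invalid.
    Invalid frames are filled by linear interpolation between neighboring
    valid tips.  Returns ``(observations, trajectory)``.
    """
    cfg = config or TrackingConfig()
    stack = frames.frames
    n = frames.n_frames
    if n == 0:
        raise ValueError("empty frame sequence")

    floor = cfg.score_floor_frac * corner_scores(stack[0], cfg.window_half_width).max()
    hint = seed_hint if seed_hint is not None else _border_hint(stack[0].shape, cfg.insertion_side)
    first = detect_tip(
        stack[0],
        seed_hint=hint,
        score_floor=floor,
        window_half_width=cfg.window_half_width,
        subpixel=cfg.subpixel,
    )
    if first is None:
        raise UnrecoverableStartError(
            "no qualifying corner in the first frame; provide a seed_hint"
        )

    thr = cfg.threshold
    if thr is None:
        f0 = stack[0]
        thr = threshold_otsu(f0) + 1 if f0.min() != f0.max() else 256

    observations = []
    prev = first[0]
    for k in range(n):
        if k == 0:
            det = first
        else:
            det = None
            for side in (cfg.roi_size, cfg.roi_size * 2):
                half = side / 2
                roi = (prev[0] - half, prev[1] - half, prev[0] + half + 1, prev[1] + half + 1)
                det = _select_tip_candidate(
                    stack[k], roi, floor, cfg.window_half_width, thr
                )
                if det is not None:
                    break
        mask = binarize_frame(stack[k], cfg.threshold) if cfg.keep_masks else None
        if det is None:
            observations.append(
                WireObservation(k, None, 0.0, valid=False, tip_source="interpolated",
                                wire_mask=mask)
            )
        else:
            tip = det[0]
            if cfg.snap_to_wire_end:
                tip = _snap_to_wire_end(stack[k], tip, thr)
            observations.append(
                WireObservation(k, tip, det[1], valid=True, tip_source="detected",
                                wire_mask=mask)
            )
            prev = tip

    _fill_invalid(observations)
    traj = _trajectory_from_observations(observations, frames.fps)
    return observations, traj


def _fill_invalid(observations):
    valid_idx = np.array([o.frame_index for o in observations if o.valid])
    if len(valid_idx) == 0:
        raise UnrecoverableStartError("no valid detections in the sequence")
    vx = np.array([observations[i].tip[0] for i in valid_idx])
    vy = np.array([observations[i].tip[1] for i in valid_idx])
    for obs in observations:
        if not obs.valid:
            x = float(np.interp(obs.frame_index, valid_idx, vx))
            y = float(np.interp(obs.frame_index, valid_idx, vy))
            obs.tip = (x, y)
            obs.tip_source = "interpolated"


def _trajectory_from_observations(observations, fps):
    idx = np.array([o.frame_index for o in observations], dtype=float)
    x = np.array([o.tip[0] for o in observations], dtype=float)
    y = np.array([o.tip[1] for o in observations], dtype=float)
    return TipTrajectory(t=idx / fps, x=x, y=y)


def apply_manual_fixes(observations, manual_points, fps: float = 20.0) -> TipTrajectory:
    """Override tip positions with manually located points.

    ``manual_points`` is a list of ``(frame_index, x, y)``.  Manual points win
    over detections and interpolations and are flagged ``tip_source="manual"``.
    Duplicate frame indices are an error.  Returns the complete trajectory.
    """
    indices = [int(p[0]) for p in manual_points]
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate frame index in manual_points")
    n = len(observations)
    for i, x, y in manual_points:
        i = int(i)
        if not (0 <= i < n):
            raise IndexError(f"manual fix index {i} out of range 0..{n - 1}")
        obs = observations[i]
        obs.tip = (float(x), float(y))
        obs.valid = True
        obs.tip_source = "manual"
    _fill_invalid(observations)
    return _trajectory_from_observations(observations, fps)


def polyline_from_mask(mask: np.ndarray, tip) -> np.ndarray | None:
    """Recover an ordered wire centerline from a binary mask.

    Skeletonizes the mask and walks the skeleton from the pixel nearest the
    tip to the farthest connected pixel (the insertion end), returning the
    polyline ordered insertion -> tip.  Returns None for an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return None
    skel = skeletonize(mask)
    pts = np.argwhere(skel)  # (y, x)
    if len(pts) == 0:
        return None
    tip = np.asarray(tip, dtype=float)
    start = int(np.argmin((pts[:, 1] - tip[0]) ** 2 + (pts[:, 0] - tip[1]) ** 2))

    skel_set = {(int(r), int(c)) for r, c in pts}
    root = (int(pts[start, 0]), int(pts[start, 1]))
    parent = {root: None}
    frontier = [root]
    far = root
    while frontier:
        nxt = []
        for r, c in frontier:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    nb = (r + dr, c + dc)
                    if nb in skel_set and nb not in parent:
                        parent[nb] = (r, c)
                        nxt.append(nb)
        if nxt:
            far = nxt[-1]
        frontier = nxt
    # path from the farthest pixel (insertion end) back to the tip
    chain = []
    node = far
    while node is not None:
        chain.append(node)
        node = parent[node]
    poly = np.array([(c, r) for r, c in chain], dtype=float)
    poly[-1] = tip  # snap the final vertex to the detected tip
    return poly
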