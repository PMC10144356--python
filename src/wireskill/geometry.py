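"""Two-dimensional vessel phantom geometry.

The phantom is the camera's view of a transparent aortic-arch model: a
descending aorta, the arch itself, and three supra-aortic branch targets
(brachiocephalic, left common carotid, left subclavian).  Everything lives in
image coordinates: origin top-left, x = column, y = row, units are pixels.

The lumen is the union of constant-radius tubes around per-segment
centerlines.  ``wall_clearance`` measures how far inside the lumen a point is
(0 at the wall), which is the quantity the collision rule thresholds.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "GeometryError",
    "Segment",
    "TaskPath",
    "VesselPhantom",
    "DEFAULT_GEOMETRY",
    "build_phantom",
    "resample_polyline",
    "polyline_arclength",
    "points_to_polyline_distance",
]


class GeometryError(ValueError):
    """Raised for non-physical phantom configurations."""


#: Default phantom geometry (pixels, degrees).  Representative of an adult
#: aortic arch viewed top-down in a 640x480 frame; not a replica of any
#: particular silicone model.
DEFAULT_GEOMETRY: dict = {
    "frame_size": [640, 480],  # (width, height)
    "arch_center": [320.0, 260.0],
    "arch_radius": 130.0,
    "arch_span_deg": [0.0, 165.0],
    "vessel_radius": 14.0,
    "descending_length": 200.0,
    # The guidewire is pre-inserted: the tip's start point sits this far above
    # the insertion end of the descending aorta, so the wire's static tail is
    # well separated from the moving tip in every frame.
    "start_margin": 60.0,
    "branches": {
        # takeoff_deg: angular position on the arch (0 = descending side);
        # direction_deg: take-off direction; length/radius in px.
        "brachiocephalic": {
            "takeoff_deg": 140.0,
            "direction_deg": 150.0,
            "length": 120.0,
            "radius": 9.0,
        },
        "left_common_carotid": {
            "takeoff_deg": 100.0,
            "direction_deg": 108.0,
            "length": 100.0,
            "radius": 8.0,
        },
        "left_subclavian": {
            "takeoff_deg": 62.0,
            "direction_deg": 75.0,
            "length": 105.0,
            "radius": 9.0,
        },
    },
    "vd_map": {
        "brachiocephalic": 1,
        "left_common_carotid": 2,
        "left_subclavian": 2,
    },
    "contact_eps": 2.0,
}


def _unit(deg: float) -> np.ndarray:
    """Unit vector for an angle in degrees, y axis pointing down (image)."""
    rad = math.radians(deg)
    return np.array([math.cos(rad), -math.sin(rad)])


def polyline_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length along a polyline, starting at 0."""
    steps = np.hypot(*np.diff(points, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(steps)])


def resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at (approximately) uniform arc-length spacing."""
    cum = polyline_arclength(points)
    total = cum[-1]
    n = max(int(round(total / spacing)) + 1, 2)
    s = np.linspace(0.0, total, n)
    x = np.interp(s, cum, points[:, 0])
    y = np.interp(s, cum, points[:, 1])
    return np.column_stack([x, y])


def resample_polyline_n(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to exactly ``n`` equally spaced vertices."""
    cum = polyline_arclength(points)
    s = np.linspace(0.0, cum[-1], n)
    return np.column_stack(
        [np.interp(s, cum, points[:, 0]), np.interp(s, cum, points[:, 1])]
    )


def points_to_polyline_distance(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Euclidean distance from each query point to a polyline.

    points : (K, 2), poly : (M, 2) with M >= 2.  Returns (K,).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    a = poly[:-1][None, :, :]
    b = poly[1:][None, :, :]
    p = points[:, None, :]
    ab = b - a
    denom = np.einsum("kmi,kmi->km", ab, ab)
    denom = np.where(denom == 0.0, 1.0, denom)
    t = np.clip(np.einsum("kmi,kmi->km", p - a, ab) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    return np.linalg.norm(p - proj, axis=-1).min(axis=1)


@dataclass(frozen=True, eq=False)
class Segment:
    """A vessel segment: an ordered centerline and a lumen half-width."""

    name: str
    centerline: np.ndarray  # (M, 2) float px
    radius: float


@dataclass(frozen=True, eq=False)
class TaskPath:
    """Arc-length parameterized centerline from the insertion point to a
    branch target, the substrate on which trials are simulated."""

    points: np.ndarray        # (M, 2) dense polyline
    cum: np.ndarray           # (M,) cumulative arc length
    radius: np.ndarray        # (M,) local lumen half-width
    bifurcation_s: tuple      # arc positions of branch mouths en route + target mouth
    exclusion_s: tuple        # (lo, hi) arc ranges near mouths (ambiguous wall side)
    total_length: float

    def point_at(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        x = np.interp(s, self.cum, self.points[:, 0])
        y = np.interp(s, self.cum, self.points[:, 1])
        return np.stack([x, y], axis=-1)

    def normal_at(self, s) -> np.ndarray:
        """Unit normal (left of travel) at arc position(s) s."""
        s = np.asarray(s, dtype=float)
        h = 2.0
        p0 = self.point_at(np.clip(s - h, 0.0, self.total_length))
        p1 = self.point_at(np.clip(s + h, 0.0, self.total_length))
        tang = p1 - p0
        norm = np.linalg.norm(tang, axis=-1, keepdims=True)
        norm = np.where(norm == 0.0, 1.0, norm)
        tang = tang / norm
        return np.stack([-tang[..., 1], tang[..., 0]], axis=-1)

    def radius_at(self, s) -> np.ndarray:
        return np.interp(np.asarray(s, dtype=float), self.cum, self.radius)

    def in_exclusion(self, s: float) -> bool:
        return any(lo <= s <= hi for lo, hi in self.exclusion_s)


@dataclass(frozen=True, eq=False)
class VesselPhantom:
    """The assembled phantom: segments, branch targets, and difficulty map."""

    segments: dict
    branches: tuple
    vd_map: dict
    contact_eps: float
    start_point: np.ndarray      # tip position at trial start
    insertion_point: np.ndarray  # where the wire enters the lumen
    frame_shape: tuple  # (height, width)
    branch_geometry: dict  # name -> {diameter, distance, angle_deg}
    config: dict = field(repr=False)
    _paths: dict = field(default_factory=dict, repr=False)

    def wall_clearance(self, points: np.ndarray) -> np.ndarray:
        """Distance from point(s) to the nearest lumen wall, measured from
        inside: equals the segment radius on a centerline, 0 on the wall,
        negative outside the lumen."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        best = np.full(len(points), -np.inf)
        for seg in self.segments.values():
            d = points_to_polyline_distance(points, seg.centerline)
            np.maximum(best, seg.radius - d, out=best)
        return best

    def task_path(self, task: str) -> TaskPath:
        if task not in self.branches:
            raise KeyError(f"unknown task/branch {task!r}; known: {self.branches}")
        if task not in self._paths:
            self._paths[task] = _build_task_path(self, task)
        return self._paths[task]


def _arc_polyline(center, radius, deg0, deg1, step_deg=1.0) -> np.ndarray:
    n = max(int(abs(deg1 - deg0) / step_deg) + 1, 2)
    degs = np.linspace(deg0, deg1, n)
    rad = np.radians(degs)
    cx, cy = center
    return np.column_stack([cx + radius * np.cos(rad), cy - radius * np.sin(rad)])


def build_phantom(geometry_config: dict | None = None) -> VesselPhantom:
    """Assemble a :class:`VesselPhantom` from a geometry config.

    Deterministic: the same config always yields byte-identical arrays.
    Raises :class:`GeometryError` for non-positive radii/lengths or branch
    take-offs whose mouths overlap on the arch.
    """
    cfg = copy.deepcopy(DEFAULT_GEOMETRY)
    if geometry_config:
        for key, val in geometry_config.items():
            if key == "branches":
                for name, bcfg in val.items():
                    cfg["branches"].setdefault(name, {}).update(bcfg)
            elif key == "vd_map":
                cfg["vd_map"].update(val)
            else:
                cfg[key] = val

    arch_c = np.asarray(cfg["arch_center"], dtype=float)
    arch_r = float(cfg["arch_radius"])
    r_vessel = float(cfg["vessel_radius"])
    desc_len = float(cfg["descending_length"])
    if arch_r <= 0 or r_vessel <= 0 or desc_len <= 0:
        raise GeometryError("arch radius, vessel radius and descending length must be > 0")

    span0, span1 = cfg["arch_span_deg"]
    arch = _arc_polyline(arch_c, arch_r, span0, span1)
    desc_top = arch[0]
    desc_bottom = desc_top + np.array([0.0, desc_len])
    descending = np.linspace(desc_bottom, desc_top, max(int(desc_len / 2), 2))

    segments = {
        "descending_aorta": Segment("descending_aorta", descending, r_vessel),
        "arch": Segment("arch", arch, r_vessel),
    }

    branch_names = tuple(sorted(cfg["branches"]))
    takeoffs = {}
    branch_geometry = {}
    for name in branch_names:
        b = cfg["branches"][name]
        radius = float(b["radius"])
        length = float(b["length"])
        if radius <= 0 or length <= 0:
            raise GeometryError(f"branch {name!r}: radius and length must be > 0")
        takeoff_deg = float(b["takeoff_deg"])
        if not (span0 < takeoff_deg < span1):
            raise GeometryError(f"branch {name!r}: take-off outside the arch span")
        p0 = arch_c + arch_r * np.array(
            [math.cos(math.radians(takeoff_deg)), -math.sin(math.radians(takeoff_deg))]
        )
        direction = _unit(float(b["direction_deg"]))
        p1 = p0 + length * direction
        centerline = np.linspace(p0, p1, max(int(length / 2), 2))
        segments[name] = Segment(name, centerline, radius)
        takeoffs[name] = (takeoff_deg, p0, radius)
        # inclination between the branch direction and the local arch tangent
        tang = np.array(
            [-math.sin(math.radians(takeoff_deg)), -math.cos(math.radians(takeoff_deg))]
        )
        cosang = float(np.clip(np.dot(direction, tang), -1.0, 1.0))
        angle_deg = math.degrees(math.acos(cosang))
        arc_from_desc = arch_r * math.radians(takeoff_deg - span0)
        branch_geometry[name] = {
            "diameter": 2.0 * radius,
            "distance": desc_len + arc_from_desc,
            "angle_deg": angle_deg,
        }

    # overlapping take-offs: branch mouths must not intersect on the arch
    for i, a in enumerate(branch_names):
        for b in branch_names[i + 1:]:
            gap = float(np.linalg.norm(takeoffs[a][1] - takeoffs[b][1]))
            if gap < takeoffs[a][2] + takeoffs[b][2]:
                raise GeometryError(f"branches {a!r} and {b!r} have overlapping take-offs")

    vd_map = {k: int(v) for k, v in cfg["vd_map"].items()}
    missing = set(branch_names) - set(vd_map)
    if missing:
        raise GeometryError(f"vd_map does not cover branches: {sorted(missing)}")

    width, height = cfg["frame_size"]
    start = desc_bottom - np.array([0.0, float(cfg["start_margin"])])
    return VesselPhantom(
        segments=segments,
        branches=branch_names,
        vd_map=vd_map,
        contact_eps=float(cfg["contact_eps"]),
        start_point=start,
        insertion_point=desc_bottom - np.array([0.0, 4.0]),
        frame_shape=(int(height), int(width)),
        branch_geometry=branch_geometry,
        config=cfg,
    )


def _build_task_path(phantom: VesselPhantom, task: str) -> TaskPath:
    cfg = phantom.config
    arch_c = np.asarray(cfg["arch_center"], dtype=float)
    arch_r = float(cfg["arch_radius"])
    span0 = float(cfg["arch_span_deg"][0])
    r_vessel = float(cfg["vessel_radius"])
    target = cfg["branches"][task]
    takeoff = float(target["takeoff_deg"])

    desc = phantom.segments["descending_aorta"].centerline
    start = phantom.start_point
    descending = np.vstack([start, desc[-1]])
    arch_part = _arc_polyline(arch_c, arch_r, span0, takeoff)
    branch = phantom.segments[task].centerline

    raw = np.vstack([descending, arch_part[1:], branch[1:]])
    points = resample_polyline(raw, 2.0)
    # fillet the take-off: a real wire bends with finite radius, it does not
    # fold at the junction vertex (a hard fold would also mimic a tip corner).
    # Linear extrapolation at both ends keeps the endpoints fixed under the
    # Gaussian smoothing; the extensions are trimmed afterwards.
    sigma = 5.0
    pad = int(4 * sigma)
    head = points[0] + np.arange(-pad, 0)[:, None] * (points[1] - points[0])
    tail = points[-1] + np.arange(1, pad + 1)[:, None] * (points[-1] - points[-2])
    extended = np.vstack([head, points, tail])
    smoothed = ndimage.gaussian_filter1d(extended, sigma=sigma, axis=0)[pad:-pad]
    points = resample_polyline(smoothed, 2.0)
    cum = polyline_arclength(points)

    # local lumen half-width along the path: vessel radius until the branch
    # mouth, branch radius beyond it
    desc_s = float(np.linalg.norm(desc[-1] - start))
    s_mouth = desc_s + arch_r * math.radians(takeoff - span0)
    radius = np.where(cum <= s_mouth, r_vessel, float(target["radius"]))

    bifs = []
    exclusions = []
    for name in phantom.branches:
        b_takeoff = float(cfg["branches"][name]["takeoff_deg"])
        if b_takeoff > takeoff:
            continue  # not encountered en route
        s_b = desc_s + arch_r * math.radians(b_takeoff - span0)
        bifs.append(s_b)
        half = phantom.segments[name].radius + r_vessel + 6.0
        exclusions.append((s_b - half, s_b + half))

    return TaskPath(
        points=points,
        cum=cum,
        radius=radius.astype(float),
        bifurcation_s=tuple(sorted(bifs)),
        exclusion_s=tuple(exclusions),
        total_length=float(cum[-1]),
    )
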