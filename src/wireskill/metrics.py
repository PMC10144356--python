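"""The nine objective performance metrics.

From a tip trajectory, wire observations, phantom geometry, a speed profile
and a contact-force trace, a trial is summarized as:

* PT  - procedure time (s)
* CN  - number of tip/wall collision episodes
* PL  - tip path length (px): sum of Euclidean steps between frames
* SPN - number of speed peaks: samples strictly exceeding their five
        predecessors, five successors, and the trial mean speed
* SV_x, SV_y - slope variations: accumulated absolute first differences of
        the tip's x and y image coordinates (px)
* VD  - vascular difficulty of the target branch (ordinal, 1 = lower)
* MF, MFV - maximum and mean of the resultant force magnitude
        sqrt(Fx^2 + Fy^2 + Fz^2) (N)

Image-plane metrics are in pixels; an optional mm-per-px calibration scalar
converts PL/SV.  Untrimmed procedure time is the span between the first and
last frame, (n - 1) / fps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import VesselPhantom, resample_polyline_n
from .tracking import TipTrajectory

__all__ = [
    "SpeedProfile",
    "ForceTrace",
    "MetricVector",
    "CollisionParams",
    "MissingStreamError",
    "path_length",
    "speed_profile",
    "count_speed_peaks",
    "slope_variation",
    "count_collisions",
    "procedure_time",
    "force_summary",
    "vascular_difficulty",
    "continuous_difficulty",
    "metric_vector",
    "FEATURE_ORDER",
    "TABLE_ROW_ORDER",
]

#: Feature order used by the classifier.
FEATURE_ORDER = (
    "procedure_time",
    "collision_count",
    "path_length",
    "speed_peak_count",
    "slope_variation_x",
    "slope_variation_y",
    "vascular_difficulty",
    "max_force",
    "mean_force",
)

#: Row order of the printed significance tables (VD is the stratifier).
TABLE_ROW_ORDER = (
    "path_length",
    "collision_count",
    "speed_peak_count",
    "slope_variation_x",
    "slope_variation_y",
    "procedure_time",
    "max_force",
    "mean_force",
)


class MissingStreamError(ValueError):
    """A required per-trial data stream is absent."""


@dataclass(eq=False)
class SpeedProfile:
    """Per-sample manipulation speed (>= 0) and its provenance."""

    v: np.ndarray
    source: str = "trajectory"  # controller | trajectory

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        if np.any(self.v < 0):
            raise ValueError("speed samples must be >= 0")

    @property
    def v_mean(self) -> float:
        return float(self.v.mean()) if len(self.v) else 0.0


@dataclass(eq=False)
class ForceTrace:
    """Raw 3-axis contact forces (N) sampled at increasing times (s)."""

    t: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.fx = np.asarray(self.fx, dtype=float)
        self.fy = np.asarray(self.fy, dtype=float)
        self.fz = np.asarray(self.fz, dtype=float)
        lengths = {len(self.t), len(self.fx), len(self.fy), len(self.fz)}
        if len(lengths) != 1:
            raise ValueError("force trace columns must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("force trace time must be strictly increasing")

    def __len__(self):
        return len(self.t)

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.fx**2 + self.fy**2 + self.fz**2)


@dataclass
class CollisionParams:
    """Thresholds of the two-frame collision rule (all in px)."""

    contact_eps: float = 2.0       # tip-to-wall contact distance
    delta_stationary: float = 1.5  # max tip motion for "stationary"
    body_change_tau: float = 1.0   # min mean body-vertex displacement
    resample_n: int = 50           # common vertex count for body comparison


@dataclass
class MetricVector:
    """The nine-feature summary of one trial."""

    procedure_time: float
    collision_count: int
    path_length: float
    speed_peak_count: int
    slope_variation_x: float
    slope_variation_y: float
    vascular_difficulty: int
    max_force: float
    mean_force: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.procedure_time <= 0:
            raise ValueError("procedure time must be > 0")
        if self.collision_count < 0 or self.speed_peak_count < 0:
            raise ValueError("counts must be >= 0")
        if self.max_force < self.mean_force:
            raise ValueError("max force cannot be below mean force")

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("provenance")
        return d


def path_length(traj: TipTrajectory) -> float:
    """Total tip path length: sum of per-frame Euclidean displacements."""
    if traj.n < 2:
        return 0.0
    return float(np.hypot(np.diff(traj.x), np.diff(traj.y)).sum())


def speed_profile(
    traj: TipTrajectory | None = None,
    fps: float | None = None,
    controller: np.ndarray | SpeedProfile | None = None,
) -> SpeedProfile:
    """Build the speed profile for a trial.

    A controller log (the master-side speed recording) is passed through
    unchanged.  Otherwise the profile is derived from the trajectory:
    v_i = Euclidean step length * fps, which needs n >= 2 samples.
    """
    if controller is not None:
        if isinstance(controller, SpeedProfile):
            return controller
        return SpeedProfile(np.asarray(controller, dtype=float), source="controller")
    if traj is None:
        raise MissingStreamError("speed: neither controller log nor trajectory given")
    if traj.n < 2:
        raise ValueError("trajectory-derived speed needs at least 2 samples")
    if fps is None:
        fps = 1.0 / float(np.median(np.diff(traj.t)))
    steps = np.hypot(np.diff(traj.x), np.diff(traj.y))
    return SpeedProfile(steps * fps, source="trajectory")


def count_speed_peaks(profile: SpeedProfile) -> int:
    """Count speed peaks: samples strictly greater than the five samples
    before them, the five after them, and the trial mean speed.

    Profiles shorter than 11 samples cannot host a peak and return 0 with a
    warning.
    """
    v = profile.v
    n = len(v)
    if n < 11:
        warnings.warn("speed profile shorter than 11 samples: no peaks countable",
                      stacklevel=2)
        return 0
    win = np.lib.stride_tricks.sliding_window_view(v, 11)
    center = win[:, 5]
    is_peak = (
        (center > win[:, :5].max(axis=1))
        & (center > win[:, 6:].max(axis=1))
        & (center > profile.v_mean)
    )
    return int(is_peak.sum())


def slope_variation(traj: TipTrajectory) -> tuple:
    """Accumulated absolute first differences of the tip coordinates.

    Returns (SV_x, SV_y) = (sum |x_{m+1} - x_m|, sum |y_{m+1} - y_m|) over all
    consecutive frame pairs.
    """
    if traj.n < 2:
        return 0.0, 0.0
    return (
        float(np.abs(np.diff(traj.x)).sum()),
        float(np.abs(np.diff(traj.y)).sum()),
    )


def count_collisions(
    observations: list,
    phantom: VesselPhantom,
    params: CollisionParams | None = None,
) -> int:
    """Count tip/wall collision episodes.

    A frame pair (t, t+1) qualifies when (a) the tip is within ``contact_eps``
    of the wall at t, (b) no non-tip wire vertex is within ``contact_eps`` of
    the wall at t, (c) at t+1 the tip has moved at most ``delta_stationary``
    px and is still within ``contact_eps`` of the wall, and (d) the non-tip
    body has changed: after arc-length resampling to ``resample_n`` vertices,
    the mean per-vertex displacement exceeds ``body_change_tau``.  Maximal
    runs of consecutive qualifying pairs count as one collision episode.
    """
    p = params or CollisionParams(contact_eps=phantom.contact_eps)
    polys = []
    tips = []
    for obs in observations:
        if obs.wire_polyline is None:
            raise MissingStreamError(
                f"wire polyline missing at frame {obs.frame_index}"
            )
        if obs.tip is None:
            raise MissingStreamError(f"tip missing at frame {obs.frame_index}")
        polys.append(np.asarray(obs.wire_polyline, dtype=float))
        tips.append(obs.tip)
    tips = np.asarray(tips, dtype=float)
    if len(tips) < 2:
        return 0

    clearance = phantom.wall_clearance(tips)
    contact = clearance <= p.contact_eps
    step = np.hypot(*np.diff(tips, axis=0).T)
    candidates = np.nonzero(contact[:-1] & contact[1:] & (step <= p.delta_stationary))[0]

    qualifying = []
    for t in candidates:
        body_t, body_t1 = polys[t][:-1], polys[t + 1][:-1]
        if len(body_t) == 0 or len(body_t1) == 0:
            continue
        if phantom.wall_clearance(body_t).min() <= p.contact_eps:
            continue  # (b): body also touches the wall
        if len(body_t) < 2 or len(body_t1) < 2:
            continue
        ra = resample_polyline_n(body_t, p.resample_n)
        rb = resample_polyline_n(body_t1, p.resample_n)
        if float(np.linalg.norm(rb - ra, axis=1).mean()) > p.body_change_tau:
            qualifying.append(int(t))

    if not qualifying:
        return 0
    episodes = 1 + int(np.sum(np.diff(qualifying) > 1))
    return episodes


def procedure_time(
    n_frames: int,
    fps: float,
    trajectory: TipTrajectory | None = None,
    trim: bool = False,
    motion_eps: float = 1.0,
) -> float:
    """Procedure time in seconds.

    Untrimmed (default): the span between the first and last frame,
    (n - 1) / fps.  With ``trim=True`` the span is restricted to the first
    and last frame where the tip moves more than ``motion_eps`` px between
    frames, which drops leading/trailing idle video.
    """
    if fps <= 0:
        raise ValueError("fps must be > 0")
    if n_frames <= 1:
        return 0.0
    if not trim:
        return (n_frames - 1) / fps
    if trajectory is None:
        raise MissingStreamError("trimming needs a tip trajectory")
    steps = np.hypot(np.diff(trajectory.x), np.diff(trajectory.y))
    moving = np.nonzero(steps > motion_eps)[0]
    if len(moving) == 0:
        return 0.0
    first, last = moving[0], moving[-1] + 1
    return (last - first) / fps


def force_summary(force: ForceTrace) -> tuple:
    """(MF, MFV): max and mean of the per-sample resultant force magnitude."""
    if len(force) == 0:
        raise ValueError("empty force trace")
    mag = force.magnitude()
    return float(mag.max()), float(mag.mean())


def vascular_difficulty(task: str, phantom: VesselPhantom) -> int:
    """Ordinal vascular difficulty of the target branch (1 = lower)."""
    if task not in phantom.vd_map:
        raise KeyError(f"branch {task!r} not in the difficulty map")
    return int(phantom.vd_map[task])


def continuous_difficulty(task: str, phantom: VesselPhantom, weights=(1.0, 0.01, 0.01)) -> float:
    """Continuous difficulty score from branch geometry.

    s = w1 * (1 / diameter) + w2 * distance + w3 * inclination angle, where
    diameter is the branch lumen diameter (px), distance the path length from
    the insertion point to the branch mouth (px) and the angle the take-off
    inclination against the arch (degrees).  Narrower, farther and steeper
    branches score higher.
    """
    if task not in phantom.branch_geometry:
        raise KeyError(f"branch {task!r} not in the phantom")
    g = phantom.branch_geometry[task]
    w1, w2, w3 = weights
    if w1 < 0 or w2 < 0 or w3 < 0:
        raise ValueError("difficulty weights must be >= 0")
    return float(w1 / g["diameter"] + w2 * g["distance"] + w3 * g["angle_deg"])


def metric_vector(
    trajectory: TipTrajectory,
    force: ForceTrace,
    phantom: VesselPhantom,
    task: str,
    fps: float,
    observations: list | None = None,
    speed: SpeedProfile | None = None,
    collision_params: CollisionParams | None = None,
    trim_time: bool = False,
    mm_per_px: float | None = None,
) -> MetricVector:
    """Assemble the nine-feature metric vector for one trial.

    The speed source defaults to the controller log when given, else the
    trajectory; collision counting needs per-frame wire polylines in
    ``observations``.  Component errors propagate, naming the missing stream.
    """
    if trajectory is None:
        raise MissingStreamError("tip trajectory")
    if force is None:
        raise MissingStreamError("force trace")
    if observations is None:
        raise MissingStreamError("wire observations (needed for collision counting)")

    prof = speed if speed is not None else speed_profile(trajectory, fps=fps)
    pt = procedure_time(trajectory.n, fps, trajectory=trajectory, trim=trim_time)
    cn = count_collisions(observations, phantom, collision_params)
    pl = path_length(trajectory)
    spn = count_speed_peaks(prof)
    sv_x, sv_y = slope_variation(trajectory)
    vd = vascular_difficulty(task, phantom)
    mf, mfv = force_summary(force)

    scale = 1.0
    unit = "px"
    if mm_per_px is not None:
        scale, unit = float(mm_per_px), "mm"
    return MetricVector(
        procedure_time=pt,
        collision_count=cn,
        path_length=pl * scale,
        speed_peak_count=spn,
        slope_variation_x=sv_x * scale,
        slope_variation_y=sv_y * scale,
        vascular_difficulty=vd,
        max_force=mf,
        mean_force=mfv,
        provenance={
            "speed_source": prof.source,
            "length_unit": unit,
            "trimmed_time": trim_time,
            "collision_params": asdict(collision_params or
                                       CollisionParams(contact_eps=phantom.contact_eps)),
        },
    )
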