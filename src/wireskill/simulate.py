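"""Skill-conditioned guidewire trial simulation with exported ground truth.

A trial drives a virtual guidewire tip along the arc-length parameterization
of a task path (descending aorta -> arch -> target branch).  The per-frame
advance speed follows a skill-conditioned AR(1) process; novices additionally
dwell, withdraw and retry at bifurcations, wander laterally, and pin the tip
against the vessel wall in contact episodes during which the wire body alone
changes shape (the event the collision rule detects).  Contact episodes also
inject half-sine spikes into the synthetic force trace.

Every stream (tip path, per-frame wire polylines, speed, force) shares the
frame count, and a trial is exactly regenerable from its recorded seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import VesselPhantom, build_phantom
from .metrics import ForceTrace, SpeedProfile
from .tracking import TipTrajectory, WireObservation

__all__ = [
    "SkillProfile",
    "SimulatedTrial",
    "CohortDesign",
    "expert_profile",
    "novice_profile",
    "simulate_trial",
    "design_trials",
    "generate_cohort",
    "trial_observations",
]

_MAX_SEED = 2**31


@dataclass(frozen=True)
class SkillProfile:
    """Parameters of a simulated operator.

    Expert defaults strictly dominate novice defaults: lower positional
    jitter, bifurcation retry probability, wall-contact rate and force-spike
    scale.
    """

    label: str
    jitter_sd: float        # lateral tip noise sd (px)
    reversal_prob: float    # per-bifurcation retry probability
    pause_prob: float       # per-step dwell probability
    contact_rate: float     # expected wall-contact episodes per trial
    force_spike_scale: float  # contact force spike amplitude (N)
    advance_speed: float = 60.0  # mean tip advance speed (px/s)
    speed_sd: float = 8.0        # AR(1) innovation sd (px/s)
    speed_rho: float = 0.9       # AR(1) persistence of the speed process
    pause_frames: tuple = (2, 8)  # dwell length range (frames)
    body_wiggle: float = 0.3     # baseline lateral body wave amplitude (px)

    def __post_init__(self):
        for name in ("reversal_prob", "pause_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("jitter_sd", "contact_rate", "force_spike_scale",
                     "advance_speed", "speed_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def expert_profile(**overrides) -> SkillProfile:
    """Default expert: smooth, monotone progress, rare wall contact."""
    base = dict(
        label="expert", jitter_sd=0.5, reversal_prob=0.05, pause_prob=0.02,
        contact_rate=0.2, force_spike_scale=0.3, advance_speed=60.0,
        speed_sd=8.0, speed_rho=0.9, body_wiggle=0.3,
    )
    base.update(overrides)
    return SkillProfile(**base)


def novice_profile(**overrides) -> SkillProfile:
    """Default novice: jittery, hesitant, retries bifurcations, hits walls."""
    base = dict(
        label="novice", jitter_sd=2.5, reversal_prob=0.5, pause_prob=0.08,
        contact_rate=3.0, force_spike_scale=1.2, advance_speed=45.0,
        speed_sd=28.0, speed_rho=0.85, body_wiggle=0.8,
    )
    base.update(overrides)
    return SkillProfile(**base)


@dataclass(eq=False)
class SimulatedTrial:
    """A synthetic trial with full ground truth."""

    truth_tip_path: TipTrajectory
    wire_polylines: list            # per-frame (M_i, 2) arrays, tip last
    truth_collisions: list          # qualifying consecutive frame pairs (t, t+1)
    truth_speed: SpeedProfile
    force: ForceTrace
    truth_progress: np.ndarray      # per-frame arc-length position (px)
    meta: dict

    @property
    def n_frames(self) -> int:
        return self.truth_tip_path.n

    @property
    def truth_collision_episodes(self) -> list:
        """Maximal runs of consecutive collision pairs, as (first, last) frames."""
        if not self.truth_collisions:
            return []
        starts = [self.truth_collisions[0][0]]
        ends = []
        for (a0, _), (b0, _) in zip(self.truth_collisions, self.truth_collisions[1:]):
            if b0 != a0 + 1:
                ends.append(a0 + 1)
                starts.append(b0)
        ends.append(self.truth_collisions[-1][0] + 1)
        return list(zip(starts, ends))


def _ar1(rng, n, rho, sd):
    """Zero-mean AR(1) series with stationary sd ``sd``."""
    out = np.empty(n)
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - rho * rho), n)
    prev = rng.normal(0.0, sd)
    for i in range(n):
        prev = rho * prev + innov[i]
        out[i] = prev
    return out


def _simulate_progress(path, skill, fps, rng, lead_idle_s, max_frames):
    """Arc-length position per frame: advance / pause / withdraw states."""
    end_s = path.total_length - 6.0
    v0 = skill.advance_speed
    rho = skill.speed_rho
    sd = skill.speed_sd

    pending = {}
    for s_b in path.bifurcation_s:
        retries = 0
        if rng.random() < skill.reversal_prob:
            retries = 1
            while retries < 3 and rng.random() < 0.35:
                retries += 1
        pending[s_b] = retries

    s_seq = [0.0] * int(round(lead_idle_s * fps))
    s = 0.0
    v = v0
    state = "advance"
    pause_left = 0
    withdraw_target = 0.0
    lo, hi = skill.pause_frames

    while s < end_s and len(s_seq) < max_frames:
        if state == "advance" and skill.pause_prob > 0 and rng.random() < skill.pause_prob:
            state = "pause"
            pause_left = int(rng.integers(lo, hi + 1))
        if state == "pause":
            s_seq.append(s)
            pause_left -= 1
            if pause_left <= 0:
                state = "advance"
            continue
        if state == "withdraw":
            s = max(s - 0.8 * v0 / fps, withdraw_target)
            s_seq.append(s)
            if s <= withdraw_target:
                state = "advance"
                v = 0.5 * v0
            continue
        # advance
        v = float(np.clip(v0 + rho * (v - v0) + sd * math.sqrt(1 - rho * rho) * rng.normal(),
                          0.0, 2.5 * v0))
        s_new = min(s + v / fps, end_s)
        fired = None
        for s_b in path.bifurcation_s:
            if pending.get(s_b, 0) > 0 and s < s_b <= s_new:
                fired = s_b
                break
        if fired is not None:
            pending[fired] -= 1
            s = fired
            s_seq.append(s)
            withdraw_target = max(s - rng.uniform(30.0, 80.0), 2.0)
            state = "withdraw"
            continue
        s = s_new
        s_seq.append(s)

    if not s_seq or s_seq[-1] < end_s:
        s_seq.append(min(s + v0 / fps, end_s) if s < end_s else end_s)
    return np.asarray(s_seq, dtype=float), int(round(lead_idle_s * fps))


def _plan_contacts(path, phantom, rng, contact_rate, s_seq, idle_n):
    """Choose contact episodes: (insert_index, duration, wall_point, s)."""
    n0 = len(s_seq)
    k = int(rng.poisson(contact_rate))
    chosen = []
    used = []
    for _ in range(k):
        placed = None
        for _attempt in range(60):
            i = int(rng.integers(idle_n + 5, max(n0 - 5, idle_n + 6)))
            if any(abs(i - j) < 4 for j in used):
                continue
            s_i = float(s_seq[i])
            # contacts only after the tip has left the straight insertion
            # stretch: there the wire body is too short to flex visibly
            if s_i < 80.0 or path.in_exclusion(s_i):
                continue
            point = path.point_at(s_i)
            normal = path.normal_at(s_i)
            r = float(path.radius_at(s_i))
            sides = [-1.0, 1.0] if rng.random() < 0.5 else [1.0, -1.0]
            for side in sides:
                wall = point + side * r * normal
                if float(phantom.wall_clearance(wall[None, :])[0]) <= 0.6:
                    # the body bows to r - 3 so only the tip vertex reaches
                    # the wall (the collision rule's "rest of the guidewire
                    # not in contact")
                    placed = (i, int(rng.integers(2, 6)), wall, s_i, side * (r - 3.0))
                    break
            if placed is not None:
                break
        if placed is not None:
            chosen.append(placed)
            used.append(placed[0])
    chosen.sort(key=lambda c: c[0])
    return chosen


def simulate_trial(
    phantom: VesselPhantom,
    skill: SkillProfile,
    task: str,
    fps: float = 20.0,
    seed: int = 0,
    lead_idle_s: float = 0.0,
    max_frames: int = 3000,
    meta: dict | None = None,
) -> SimulatedTrial:
    """Simulate one catheterization trial.

    The tip starts at the fixed descending-aorta start point and ends inside
    the target branch.  Identical inputs and seed give identical output.
    """
    if task not in phantom.branches:
        raise KeyError(f"unknown task {task!r}; known: {phantom.branches}")
    if fps <= 0:
        raise ValueError("fps must be > 0")
    rng = np.random.default_rng(seed)
    path = phantom.task_path(task)

    s_seq, idle_n = _simulate_progress(path, skill, fps, rng, lead_idle_s, max_frames)

    # lateral jitter: smooth AR(1) offset, clipped well clear of the wall
    n0 = len(s_seq)
    offsets = _ar1(rng, n0, 0.85, skill.jitter_sd) if skill.jitter_sd > 0 else np.zeros(n0)
    # clip by the actual wall clearance of the path point so jitter alone can
    # never put the tip into wall contact
    clearance = phantom.wall_clearance(path.point_at(s_seq))
    max_off = np.maximum(clearance - phantom.contact_eps - 2.0, 0.0)
    offsets = np.clip(offsets, -max_off, max_off)

    contacts = _plan_contacts(path, phantom, rng, skill.contact_rate, s_seq, idle_n)

    # expand the timeline: each episode freezes s at the chosen frame
    s_final = []
    off_final = []
    episode_ranges = []  # (first_frame, last_frame, wall_point)
    cursor = 0
    for (i, dur, wall, s_i, off_ep) in contacts:
        s_final.extend(s_seq[cursor:i])
        off_final.extend(offsets[cursor:i])
        start = len(s_final)
        s_final.extend([s_i] * dur)
        off_final.extend([off_ep] * dur)  # tip pinned at the wall offset
        episode_ranges.append((start, start + dur - 1, wall))
        cursor = i
    s_final.extend(s_seq[cursor:])
    off_final.extend(offsets[cursor:])
    s_arr = np.asarray(s_final)
    off_arr = np.asarray(off_final)
    n = len(s_arr)

    # tip positions
    tips = path.point_at(s_arr) + off_arr[:, None] * path.normal_at(s_arr)
    episode_frames = np.zeros(n, dtype=bool)
    for a, b, wall in episode_ranges:
        tips[a : b + 1] = wall
        episode_frames[a : b + 1] = True

    # per-frame wire body polylines (insertion -> tip); the wire is
    # pre-inserted, so a static tail runs from the insertion point up to the
    # path start in every frame
    n_tail = max(int(np.linalg.norm(phantom.insertion_point - phantom.start_point) / 4.0), 2)
    tail = np.linspace(phantom.insertion_point, phantom.start_point, n_tail + 1)[:-1]
    base_phase = np.cumsum(rng.normal(0.0, 0.15, n))
    polylines = []
    bump = 0.0
    for j in range(n):
        s_j = s_arr[j]
        body_s = np.arange(0.0, max(s_j - 2.0, 4.0), 4.0)
        pts = path.point_at(body_s)
        nrm = path.normal_at(body_s)
        taper = np.clip((s_j - body_s) / 25.0, 0.0, 1.0) * np.clip(body_s / 10.0, 0.0, 1.0)
        disp = skill.body_wiggle * np.sin(2 * np.pi * body_s / 150.0 + base_phase[j]) * taper
        # blend the tip's lateral offset into the last ~20 px of the body so
        # the wire reaches the tip without a fold (smoothstep: curvature-free
        # at both ends of the blend)
        ramp = np.clip(1.0 - (s_j - body_s) / 20.0, 0.0, 1.0)
        disp = disp + off_arr[j] * ramp * ramp * (3.0 - 2.0 * ramp)
        if episode_frames[j]:
            # while the tip is pinned, flex the body as a half-sine bow whose
            # amplitude flips sign every frame: consecutive contact frames
            # always differ by a clearly visible body-shape change
            sign = -math.copysign(1.0, bump) if (j > 0 and episode_frames[j - 1]) \
                else (1.0 if rng.random() < 0.5 else -1.0)
            bump = sign * rng.uniform(2.5, 4.0)
            disp = disp + bump * np.sin(np.pi * body_s / max(s_j, 1.0))
        poly = pts + disp[:, None] * nrm
        polylines.append(np.vstack([tail, poly, tips[j]]))

    # ground-truth collision pairs: consecutive frames inside one episode
    truth_pairs = []
    for a, b, _ in episode_ranges:
        truth_pairs.extend((t, t + 1) for t in range(a, b))

    # controller-style speed log: |ds| * fps, first sample 0
    v = np.concatenate([[0.0], np.abs(np.diff(s_arr)) * fps])
    truth_speed = SpeedProfile(v, source="controller")

    # force trace: baseline sensor noise plus contact-correlated spikes
    t = np.arange(n) / fps
    f = rng.normal(0.0, 0.05, (n, 3))
    for a, b, _ in episode_ranges:
        dur = b - a + 1
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        amp = skill.force_spike_scale * rng.uniform(0.7, 1.3)
        envelope = np.sin(np.pi * (np.arange(dur) + 0.5) / dur)
        f[a : b + 1] += amp * envelope[:, None] * direction
    force = ForceTrace(t=t, fx=f[:, 0], fy=f[:, 1], fz=f[:, 2])

    info = {"group": skill.label, "task": task, "seed": int(seed), "fps": float(fps),
            "surgeon_id": None, "repetition": None}
    if meta:
        info.update(meta)
    return SimulatedTrial(
        truth_tip_path=TipTrajectory(t=t, x=tips[:, 0], y=tips[:, 1]),
        wire_polylines=polylines,
        truth_collisions=truth_pairs,
        truth_speed=truth_speed,
        force=force,
        truth_progress=s_arr,
        meta=info,
    )


def trial_observations(trial: SimulatedTrial) -> list:
    """Ground-truth per-frame observations of a simulated trial."""
    return [
        WireObservation(
            frame_index=j,
            tip=(float(trial.truth_tip_path.x[j]), float(trial.truth_tip_path.y[j])),
            valid=True,
            tip_source="simulated",
            wire_polyline=trial.wire_polylines[j],
        )
        for j in range(trial.n_frames)
    ]


@dataclass(frozen=True)
class CohortDesign:
    """The experimental design: groups x surgeons x tasks x repetitions."""

    surgeons_per_group: int = 3
    repetitions: int = 5
    tasks: tuple = (
        "brachiocephalic",
        "brachiocephalic",
        "left_common_carotid",
        "left_subclavian",
        "left_common_carotid",
    )
    profiles: dict = field(default_factory=lambda: {
        "expert": expert_profile(), "novice": novice_profile(),
    })
    fps: float = 20.0

    @property
    def n_trials(self) -> int:
        return len(self.profiles) * self.surgeons_per_group * len(self.tasks) * self.repetitions


def design_trials(design: CohortDesign, seed: int = 0) -> list:
    """Enumerate the trial specs of a design, with deterministic per-trial seeds.

    Trial count = groups x surgeons x tasks x repetitions.
    """
    if design.surgeons_per_group < 1 or design.repetitions < 1 or not design.tasks:
        raise ValueError("design counts must be >= 1")
    n = design.n_trials
    seeds = np.random.SeedSequence(int(seed)).generate_state(n) % _MAX_SEED
    specs = []
    i = 0
    for group in sorted(design.profiles):
        for surgeon in range(design.surgeons_per_group):
            for task_idx, task in enumerate(design.tasks):
                for rep in range(design.repetitions):
                    specs.append({
                        "trial_id": f"{group[0].upper()}{surgeon + 1}_t{task_idx + 1}_r{rep + 1}",
                        "group": group,
                        "surgeon_id": f"{group[0].upper()}{surgeon + 1}",
                        "task": task,
                        "repetition": rep + 1,
                        "seed": int(seeds[i]),
                    })
                    i += 1
    return specs


def generate_cohort(
    design: CohortDesign | None = None,
    seed: int = 0,
    phantom: VesselPhantom | None = None,
) -> list:
    """Simulate a full cohort per the design (default: 2 groups x 3 surgeons
    x 5 tasks x 5 repetitions = 150 trials)."""
    design = design or CohortDesign()
    phantom = phantom or build_phantom()
    trials = []
    for spec in design_trials(design, seed):
        skill = design.profiles[spec["group"]]
        trial = simulate_trial(
            phantom, skill, spec["task"], fps=design.fps, seed=spec["seed"],
            meta={"surgeon_id": spec["surgeon_id"], "repetition": spec["repetition"],
                  "trial_id": spec["trial_id"]},
        )
        trials.append(trial)
    return trials
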