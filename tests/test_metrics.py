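import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from wireskill import (
    CollisionParams,
    ForceTrace,
    SpeedProfile,
    TipTrajectory,
    WireObservation,
    count_collisions,
    count_speed_peaks,
    force_summary,
    metric_vector,
    path_length,
    procedure_time,
    slope_variation,
    speed_profile,
    vascular_difficulty,
)
from wireskill.metrics import MissingStreamError, continuous_difficulty
from wireskill.pipeline import trial_metric_vector
from wireskill.simulate import trial_observations


def make_traj(points, fps=20.0):
    pts = np.asarray(points, dtype=float)
    return TipTrajectory(t=np.arange(len(pts)) / fps, x=pts[:, 0], y=pts[:, 1])


# ---------------------------------------------------------------- oracles

def oracle_path_length(x, y):
    return sum(
        ((x[i + 1] - x[i]) ** 2 + (y[i + 1] - y[i]) ** 2) ** 0.5
        for i in range(len(x) - 1)
    )


def oracle_slope_variation(x, y):
    return (
        sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1)),
        sum(abs(y[i + 1] - y[i]) for i in range(len(y) - 1)),
    )


def oracle_speed_peaks(v):
    v = list(v)
    n = len(v)
    if n < 11:
        return 0
    vmean = sum(v) / n
    count = 0
    for i in range(5, n - 5):
        before = v[i - 5 : i]
        after = v[i + 1 : i + 6]
        if all(v[i] > b for b in before) and all(v[i] > a for a in after) and v[i] > vmean:
            count += 1
    return count


def oracle_force_summary(fx, fy, fz):
    mags = [(a * a + b * b + c * c) ** 0.5 for a, b, c in zip(fx, fy, fz)]
    return max(mags), sum(mags) / len(mags)


# ---------------------------------------------------------------- path length

@pytest.mark.parametrize(
    "points,expected",
    [([(0, 0)], 0.0), ([(0, 0), (3, 4)], 5.0), ([(0, 0), (0, 10), (10, 10)], 20.0)],
)
def test_path_length_examples(points, expected):
    assert path_length(make_traj(points)) == pytest.approx(expected)


def test_path_length_matches_oracle_on_random_walks(rng):
    for _ in range(1000):
        pts = rng.normal(size=(rng.integers(2, 40), 2)).cumsum(axis=0)
        traj = make_traj(pts)
        assert path_length(traj) == pytest.approx(
            oracle_path_length(pts[:, 0], pts[:, 1]), rel=1e-9
        )


def test_path_length_at_least_endpoint_distance(rng):
    for _ in range(200):
        pts = rng.normal(size=(20, 2)).cumsum(axis=0)
        straight = float(np.linalg.norm(pts[-1] - pts[0]))
        assert path_length(make_traj(pts)) >= straight - 1e-12


# ---------------------------------------------------------------- speed

def test_constant_trajectory_has_zero_speed():
    prof = speed_profile(make_traj([(5, 5)] * 20), fps=20.0)
    assert np.all(prof.v == 0.0) and prof.v_mean == 0.0


def test_uniform_motion_speed_is_step_times_fps():
    pts = [(0, 2 * k) for k in range(30)]
    prof = speed_profile(make_traj(pts), fps=20.0)
    assert np.allclose(prof.v, 40.0)


def test_controller_log_passes_through_unchanged(rng):
    v = rng.uniform(0, 50, 100)
    prof = speed_profile(controller=v)
    assert prof.source == "controller"
    assert np.array_equal(prof.v, v)


def test_single_sample_trajectory_speed_rejected():
    with pytest.raises(ValueError):
        speed_profile(make_traj([(0, 0)]), fps=20.0)


def test_constant_positive_profile_has_no_peaks():
    assert count_speed_peaks(SpeedProfile(np.full(50, 3.0))) == 0


def test_single_triangular_pulse_is_one_peak():
    v = np.zeros(20)
    v[5:14] = [1, 2, 3, 4, 5, 4, 3, 2, 1]  # apex at index 9 (1-based i=10)
    assert count_speed_peaks(SpeedProfile(v)) == 1


def test_speed_peaks_match_literal_rule_on_random_profiles(rng):
    for _ in range(1000):
        v = np.abs(rng.normal(2.0, 1.5, rng.integers(11, 80)))
        assert count_speed_peaks(SpeedProfile(v)) == oracle_speed_peaks(v)


def test_short_profile_returns_zero_with_warning():
    with pytest.warns(UserWarning):
        assert count_speed_peaks(SpeedProfile(np.ones(5))) == 0


def test_peak_count_invariant_under_positive_affine_maps(rng):
    for _ in range(500):
        v = np.abs(rng.normal(2.0, 1.5, rng.integers(11, 60)))
        a = rng.uniform(0.1, 10.0)
        b = rng.uniform(0.0, 5.0)
        assert count_speed_peaks(SpeedProfile(v)) == count_speed_peaks(
            SpeedProfile(a * v + b)
        )


# ---------------------------------------------------------------- slope variation

def test_monotone_coordinate_telescopes():
    pts = [(x, 0) for x in (0, 5, 30, 77, 100)]
    sv_x, sv_y = slope_variation(make_traj(pts))
    assert sv_x == pytest.approx(100.0)
    assert sv_y == 0.0


def test_zigzag_accumulates():
    pts = [(0, 0), (10, 0), (0, 0), (10, 0)]
    assert slope_variation(make_traj(pts))[0] == pytest.approx(30.0)


def test_slope_variation_matches_oracle(rng):
    for _ in range(1000):
        pts = rng.normal(size=(rng.integers(2, 40), 2)).cumsum(axis=0)
        got = slope_variation(make_traj(pts))
        want = oracle_slope_variation(pts[:, 0], pts[:, 1])
        assert got[0] == pytest.approx(want[0], rel=1e-9)
        assert got[1] == pytest.approx(want[1], rel=1e-9)


def test_slope_variation_bounds_net_displacement(rng):
    for _ in range(200):
        x = rng.normal(size=15).cumsum()
        pts = np.column_stack([x, np.zeros(15)])
        sv_x, _ = slope_variation(make_traj(pts))
        assert sv_x >= abs(x[-1] - x[0]) - 1e-12
    # equality iff monotone
    mono = np.sort(rng.normal(size=15))
    pts = np.column_stack([mono, np.zeros(15)])
    assert slope_variation(make_traj(pts))[0] == pytest.approx(mono[-1] - mono[0])


# ---------------------------------------------------------------- procedure time

def test_procedure_time_span_convention():
    assert procedure_time(201, 20.0) == pytest.approx(10.0)
    assert procedure_time(1, 20.0) == 0.0


def test_trimming_removes_leading_idle(phantom):
    from wireskill import expert_profile, simulate_trial

    skill = expert_profile(jitter_sd=0.0)
    trial = simulate_trial(phantom, skill, "left_subclavian", seed=9, lead_idle_s=2.0)
    traj = trial.truth_tip_path
    full = procedure_time(traj.n, 20.0)
    trimmed = procedure_time(traj.n, 20.0, trajectory=traj, trim=True)
    assert full - trimmed == pytest.approx(2.0, abs=0.1)


# ---------------------------------------------------------------- force

def test_constant_force_vector_summary():
    tr = ForceTrace(t=np.arange(5) / 20, fx=np.full(5, 3.0), fy=np.full(5, 4.0),
                    fz=np.zeros(5))
    mf, mfv = force_summary(tr)
    assert mf == pytest.approx(5.0) and mfv == pytest.approx(5.0)


def test_force_summary_matches_oracle_and_max_bounds_mean(rng):
    for _ in range(1000):
        n = rng.integers(1, 50)
        f = rng.normal(size=(n, 3))
        tr = ForceTrace(t=np.arange(n) * 0.05, fx=f[:, 0], fy=f[:, 1], fz=f[:, 2])
        mf, mfv = force_summary(tr)
        omf, omfv = oracle_force_summary(f[:, 0], f[:, 1], f[:, 2])
        assert mf == pytest.approx(omf, rel=1e-9)
        assert mfv == pytest.approx(omfv, rel=1e-9)
        assert mf >= mfv


def test_force_summary_invariant_under_rotation(rng):
    n = 60
    f = rng.normal(size=(n, 3))
    base = force_summary(ForceTrace(np.arange(n) * 0.05, f[:, 0], f[:, 1], f[:, 2]))
    for _ in range(20):
        g = f @ Rotation.random(random_state=rng.integers(2**31)).as_matrix().T
        rot = force_summary(ForceTrace(np.arange(n) * 0.05, g[:, 0], g[:, 1], g[:, 2]))
        assert rot[0] == pytest.approx(base[0], rel=1e-9)
        assert rot[1] == pytest.approx(base[1], rel=1e-9)


def test_empty_force_trace_rejected():
    tr = ForceTrace(t=np.array([]), fx=np.array([]), fy=np.array([]), fz=np.array([]))
    with pytest.raises(ValueError):
        force_summary(tr)


# ---------------------------------------------------------------- difficulty

def test_vascular_difficulty_levels(phantom):
    assert vascular_difficulty("brachiocephalic", phantom) == 1
    assert vascular_difficulty("left_subclavian", phantom) == 2
    with pytest.raises(KeyError):
        vascular_difficulty("renal", phantom)


def test_continuous_difficulty_decreases_with_diameter(phantom, rng):
    import copy

    for _ in range(20):
        w = tuple(rng.uniform(0, 2, 3))
        base = continuous_difficulty("left_subclavian", phantom, weights=w)
        wide = copy.deepcopy(phantom.branch_geometry)
        wide["left_subclavian"]["diameter"] *= 2
        fat = type(phantom)(**{**phantom.__dict__, "branch_geometry": wide})
        assert continuous_difficulty("left_subclavian", fat, weights=w) <= base


# ---------------------------------------------------------------- collisions

def _stationary_wall_scenario(phantom, body_shift=5.0, tip_move=0.0, move_body=True):
    """Three frames: tip pinned at the descending-aorta wall, straight body."""
    wall_x = 450.0 + 14.0  # descending centerline x=450, radius 14
    tip = np.array([wall_x, 350.0])
    body_y = np.arange(430.0, 352.0, -6.0)

    def wire(shift, tip_pt):
        body = np.column_stack([np.full_like(body_y, 450.0 + shift), body_y])
        return np.vstack([body, tip_pt])

    frames = [
        wire(0.0, tip),
        wire(body_shift if move_body else 0.0, tip + [tip_move, 0.0]),
        wire(body_shift if move_body else 0.0, tip + [tip_move, 0.0] + [-10, 0]),
    ]
    return [
        WireObservation(i, tuple(p[-1]), wire_polyline=p, tip_source="simulated")
        for i, p in enumerate(frames)
    ]


def test_scripted_wall_pin_counts_one_collision(phantom):
    obs = _stationary_wall_scenario(phantom)
    assert count_collisions(obs, phantom) == 1


def test_no_collision_when_tip_clears_the_wall(phantom):
    obs = _stationary_wall_scenario(phantom)
    for o in obs:  # pull the tip to the centerline
        o.tip = (450.0, o.tip[1])
        o.wire_polyline = np.vstack([o.wire_polyline[:-1], [450.0, o.tip[1]]])
    assert count_collisions(obs, phantom) == 0


def test_no_collision_when_the_tip_keeps_moving(phantom):
    obs = _stationary_wall_scenario(phantom, tip_move=5.0)
    assert count_collisions(obs, phantom) == 0


def test_no_collision_without_body_morphology_change(phantom):
    obs = _stationary_wall_scenario(phantom, move_body=False)
    assert count_collisions(obs, phantom) == 0


def test_no_collision_when_the_body_also_touches_the_wall(phantom):
    obs = _stationary_wall_scenario(phantom)
    poly = obs[0].wire_polyline.copy()
    poly[:-1, 0] = 463.0  # body parked against the wall
    obs[0].wire_polyline = poly
    assert count_collisions(obs, phantom) == 0


def test_consecutive_qualifying_pairs_merge_into_one_episode(phantom):
    obs = _stationary_wall_scenario(phantom)
    # duplicate the deformation frame: pairs (0,1) and (1,2) both qualify
    extra = _stationary_wall_scenario(phantom, body_shift=10.0)[1]
    extra.frame_index = 2
    tail = obs[2]
    tail.frame_index = 3
    assert count_collisions([obs[0], obs[1], extra, tail], phantom) == 1


def test_expert_trial_with_no_contacts_counts_zero(phantom, expert_trial):
    obs = trial_observations(expert_trial)
    assert count_collisions(obs, phantom) == len(expert_trial.truth_collision_episodes)


def test_missing_polyline_rejected(phantom):
    obs = [WireObservation(0, (1.0, 1.0)), WireObservation(1, (1.0, 1.0))]
    with pytest.raises(MissingStreamError):
        count_collisions(obs, phantom)


# ---------------------------------------------------------------- aggregation

def test_metric_vector_composes_componentwise(phantom, novice_trial):
    mv = trial_metric_vector(novice_trial, phantom)
    traj = novice_trial.truth_tip_path
    assert mv.path_length == pytest.approx(path_length(traj))
    sv = slope_variation(traj)
    assert (mv.slope_variation_x, mv.slope_variation_y) == pytest.approx(sv)
    assert mv.speed_peak_count == count_speed_peaks(novice_trial.truth_speed)
    mf, mfv = force_summary(novice_trial.force)
    assert mv.max_force == pytest.approx(mf)
    assert mv.mean_force == pytest.approx(mfv)
    assert mv.collision_count == count_collisions(
        trial_observations(novice_trial), phantom
    )
    assert mv.vascular_difficulty == 2
    assert mv.procedure_time == pytest.approx((traj.n - 1) / 20.0)
    assert mv.provenance["speed_source"] == "controller"


def test_missing_streams_raise_named_errors(phantom, novice_trial):
    traj = novice_trial.truth_tip_path
    with pytest.raises(MissingStreamError, match="force"):
        metric_vector(trajectory=traj, force=None, phantom=phantom,
                      task="left_common_carotid", fps=20.0,
                      observations=trial_observations(novice_trial))
    with pytest.raises(MissingStreamError, match="observation"):
        metric_vector(trajectory=traj, force=novice_trial.force, phantom=phantom,
                      task="left_common_carotid", fps=20.0, observations=None)


def test_expert_cohort_means_lie_below_novice_means(phantom, fast_expert, fast_novice):
    from wireskill import CohortDesign, generate_cohort
    from wireskill.pipeline import cohort_metrics

    design = CohortDesign(surgeons_per_group=2, repetitions=2,
                          tasks=("left_common_carotid", "left_subclavian"),
                          profiles={"expert": fast_expert, "novice": fast_novice})
    df = cohort_metrics(generate_cohort(design, seed=31, phantom=phantom), phantom)
    means = df.groupby("group").mean(numeric_only=True)
    for col in ("path_length", "collision_count", "speed_peak_count",
                "slope_variation_x", "slope_variation_y", "procedure_time"):
        assert means.loc["expert", col] < means.loc["novice", col]


def test_mm_calibration_scales_image_metrics_only(phantom, novice_trial):
    px = trial_metric_vector(novice_trial, phantom)
    mm = trial_metric_vector(novice_trial, phantom, mm_per_px=0.5)
    assert mm.path_length == pytest.approx(0.5 * px.path_length)
    assert mm.slope_variation_y == pytest.approx(0.5 * px.slope_variation_y)
    assert mm.procedure_time == px.procedure_time
    assert mm.max_force == px.max_force
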