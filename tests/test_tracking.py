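import numpy as np
import pytest

from wireskill import (
    FrameSequence,
    TrackingConfig,
    apply_manual_fixes,
    binarize_frame,
    corner_scores,
    detect_tip,
    track_sequence,
)
from wireskill.tracking import UnrecoverableStartError, polyline_from_mask


def brute_force_corner_scores(image, w):
    """Literal per-pixel structure-tensor eigen computation (zero padding)."""
    img = np.asarray(image, dtype=float)
    h, wd = img.shape
    gx = np.zeros_like(img)
    gy = np.zeros_like(img)
    gx[:, 1:-1] = (img[:, 2:] - img[:, :-2]) / 2
    gx[:, 0] = img[:, 1] - img[:, 0]
    gx[:, -1] = img[:, -1] - img[:, -2]
    gy[1:-1, :] = (img[2:, :] - img[:-2, :]) / 2
    gy[0, :] = img[1, :] - img[0, :]
    gy[-1, :] = img[-1, :] - img[-2, :]
    out = np.zeros_like(img)
    for y in range(h):
        for x in range(wd):
            y0, y1 = max(y - w, 0), min(y + w + 1, h)
            x0, x1 = max(x - w, 0), min(x + w + 1, wd)
            sx = gx[y0:y1, x0:x1].ravel()
            sy = gy[y0:y1, x0:x1].ravel()
            m = np.array([[np.dot(sx, sx), np.dot(sx, sy)],
                          [np.dot(sx, sy), np.dot(sy, sy)]])
            out[y, x] = max(np.linalg.eigvalsh(m)[0], 0.0)
    return out


def draw_l_corner(size=48, vertex=(30, 18), arm=14, lo=30, hi=220):
    frame = np.full((size, size), lo, dtype=np.uint8)
    vx, vy = vertex
    frame[vy, vx - arm : vx + 1] = hi   # horizontal arm ending at the vertex
    frame[vy : vy + arm, vx] = hi       # vertical arm starting at the vertex
    return frame


class TestBinarize:
    def test_uniform_frame_below_threshold_gives_empty_mask(self):
        assert not binarize_frame(np.full((20, 20), 30, np.uint8), 128).any()

    def test_fixed_threshold_is_definitional(self, rng):
        frame = rng.integers(0, 256, size=(40, 50)).astype(np.uint8)
        for t in (1, 100, 128, 255):
            assert np.array_equal(binarize_frame(frame, t), frame >= t)

    def test_raising_the_threshold_never_grows_the_mask(self, rng):
        frame = rng.integers(0, 256, size=(30, 30)).astype(np.uint8)
        prev = binarize_frame(frame, 10)
        for t in (60, 120, 200):
            cur = binarize_frame(frame, t)
            assert not np.any(cur & ~prev)
            prev = cur

    def test_automatic_threshold_separates_wire_from_background(self, rng):
        frame = np.full((60, 60), 30, np.int16) + rng.integers(-3, 4, (60, 60))
        frame[20:23, 10:50] = 220 + rng.integers(-3, 4, (3, 40))
        frame = np.clip(frame, 0, 255).astype(np.uint8)
        mask = binarize_frame(frame)
        truth = np.zeros((60, 60), bool)
        truth[20:23, 10:50] = True
        assert np.array_equal(mask, truth)


class TestCornerScores:
    def test_uniform_frame_scores_zero(self):
        assert corner_scores(np.full((30, 30), 77, np.uint8)).max() == 0.0

    @pytest.mark.parametrize("w", [1, 2, 3])
    def test_matches_brute_force_eigen_oracle(self, rng, w):
        frame = rng.integers(0, 256, size=(24, 27)).astype(np.uint8)
        fast = corner_scores(frame, w)
        slow = brute_force_corner_scores(frame, w)
        # identical away from the border (the oracle clips windows there,
        # the implementation zero-pads)
        interior = (slice(w, -w), slice(w, -w))
        assert np.allclose(fast[interior], slow[interior], rtol=1e-6, atol=1e-6)

    def test_l_corner_peak_sits_at_the_vertex(self):
        frame = draw_l_corner()
        scores = corner_scores(frame, 2)
        peak = np.unravel_index(np.argmax(scores), scores.shape)
        assert abs(peak[1] - 30) <= 1 and abs(peak[0] - 18) <= 1

    def test_window_larger_than_frame_rejected(self):
        with pytest.raises(ValueError):
            corner_scores(np.zeros((3, 3), np.uint8), window_half_width=2)


class TestDetectTip:
    def test_blank_roi_reports_detection_failure(self):
        frame = draw_l_corner()
        det = detect_tip(frame, roi=(0, 35, 12, 47), score_floor=10.0)
        assert det is None

    def test_equal_corners_tie_break_smaller_y_then_x(self):
        frame = np.full((40, 40), 30, np.uint8)
        # two identical isolated bright squares: equal corner landscapes
        frame[5:8, 10:13] = 220
        frame[9:12, 10:13] = 0  # keep them separated
        frame[20:23, 10:13] = 220
        det = detect_tip(frame, score_floor=1.0)
        assert det is not None
        x, y = det[0]
        assert y < 15  # the upper structure wins


    def test_seed_hint_selects_the_nearest_qualifying_corner(self):
        frame = np.full((60, 60), 30, np.uint8)
        frame[10:13, 10:13] = 220
        frame[45:48, 45:48] = 220
        near_low = detect_tip(frame, seed_hint=(46, 46), score_floor=1.0)
        near_high = detect_tip(frame, seed_hint=(11, 11), score_floor=1.0)
        assert np.hypot(near_low[0][0] - 46, near_low[0][1] - 46) < 6
        assert np.hypot(near_high[0][0] - 11, near_high[0][1] - 11) < 6


def _line_frame(tip=(40, 12), tail=(40, 55), size=64, thick=True):
    frame = np.full((size, size), 30, np.uint8)
    x = tip[0]
    frame[tip[1] : tail[1] + 1, x] = 220
    if thick:
        frame[tip[1] : tail[1] + 1, x - 1] = 220
        frame[tip[1] : tail[1] + 1, x + 1] = 220
    return frame


class TestTrackSequence:
    def test_identical_frames_give_a_constant_valid_trajectory(self):
        frame = _line_frame()
        seq = FrameSequence(np.stack([frame] * 8), fps=20.0)
        obs, traj = track_sequence(seq, seed_hint=(40, 12))
        assert all(o.valid for o in obs)
        assert np.allclose(traj.x, traj.x[0])
        assert np.allclose(traj.y, traj.y[0])
        assert np.hypot(traj.x[0] - 40, traj.y[0] - 12) <= 2.0

    def test_blanked_frame_is_interpolated_without_shortening(self):
        frames = np.stack([_line_frame(tip=(40, 12 + k)) for k in range(9)])
        frames[4] = 30  # wire vanishes for one frame
        obs, traj = track_sequence(FrameSequence(frames, fps=20.0), seed_hint=(40, 12))
        assert traj.n == 9
        assert not obs[4].valid
        assert obs[4].tip_source == "interpolated"
        # interpolation lands between the neighbors
        assert obs[3].tip[1] <= obs[4].tip[1] <= obs[5].tip[1]

    def test_tracking_is_translation_equivariant(self):
        base = [_line_frame(tip=(30, 10 + k), tail=(30, 50)) for k in range(6)]
        seq0 = FrameSequence(np.stack(base), fps=20.0)
        dx, dy = 7, 5
        shifted = np.stack([np.roll(np.roll(f, dy, axis=0), dx, axis=1) for f in base])
        seq1 = FrameSequence(shifted, fps=20.0)
        _, t0 = track_sequence(seq0, seed_hint=(30, 10))
        _, t1 = track_sequence(seq1, seed_hint=(30 + dx, 10 + dy))
        assert np.allclose(t1.x - t0.x, dx)
        assert np.allclose(t1.y - t0.y, dy)

    def test_uniform_first_frame_is_unrecoverable(self):
        frames = np.full((4, 32, 32), 30, np.uint8)
        with pytest.raises(UnrecoverableStartError):
            track_sequence(FrameSequence(frames, fps=20.0))

    def test_trajectory_time_base_is_frame_index_over_fps(self):
        frame = _line_frame()
        seq = FrameSequence(np.stack([frame] * 5), fps=25.0)
        _, traj = track_sequence(seq, seed_hint=(40, 12))
        assert np.allclose(traj.t, np.arange(5) / 25.0)


class TestManualFixes:
    def _observations(self):
        frames = np.stack([_line_frame(tip=(40, 12 + k)) for k in range(6)])
        frames[3] = 30
        return track_sequence(FrameSequence(frames, fps=20.0), seed_hint=(40, 12))[0]

    def test_empty_fixes_leave_the_trajectory_unchanged(self):
        obs = self._observations()
        before = [(o.tip, o.tip_source) for o in obs]
        traj = apply_manual_fixes(obs, [], fps=20.0)
        assert [(o.tip, o.tip_source) for o in obs] == before
        assert traj.n == 6

    def test_fix_overrides_an_invalid_frame(self):
        obs = self._observations()
        traj = apply_manual_fixes(obs, [(3, 40.0, 15.0)], fps=20.0)
        assert obs[3].tip_source == "manual"
        assert traj.x[3] == 40.0 and traj.y[3] == 15.0

    def test_fix_overrides_a_valid_frame_too(self):
        obs = self._observations()
        apply_manual_fixes(obs, [(0, 1.0, 2.0)], fps=20.0)
        assert obs[0].tip == (1.0, 2.0)
        assert obs[0].tip_source == "manual"

    def test_duplicate_fix_indices_rejected(self):
        obs = self._observations()
        with pytest.raises(ValueError):
            apply_manual_fixes(obs, [(3, 1, 1), (3, 2, 2)], fps=20.0)

    def test_out_of_range_fix_rejected(self):
        obs = self._observations()
        with pytest.raises(IndexError):
            apply_manual_fixes(obs, [(99, 1, 1)], fps=20.0)


def test_polyline_from_mask_orders_insertion_to_tip():
    frame = _line_frame(tip=(40, 12), tail=(40, 55))
    mask = binarize_frame(frame, 128)
    poly = polyline_from_mask(mask, tip=(40.0, 12.0))
    assert poly is not None
    assert np.allclose(poly[-1], (40.0, 12.0))
    assert poly[0][1] > 50  # starts at the tail end
    assert polyline_from_mask(np.zeros((10, 10), bool), (1, 1)) is None
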