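import numpy as np
import pytest

import fishgait as fg
from fishgait import kinematics as K

from conftest import series_from_sim


def straight_track(n=20, step_px=1.0, fps=100.0, mm_per_px=0.1):
    frames = []
    for i in range(n):
        x0 = i * step_px
        S = np.column_stack([x0 + np.linspace(0, 45, 10), np.full(10, 50.0)])
        frames.append(
            fg.FrameMidline(i, C=np.array([x0 + 22.0, 50.0]), S=S,
                            head=np.array([x0 + 50.0, 50.0]))
        )
    return fg.TrackSeries(fps=fps, mm_per_px=mm_per_px, frames=frames)


class TestDeriveSeries:
    def test_stationary_fish_zero_speed(self):
        ks = K.derive_series(straight_track(step_px=0.0))
        assert np.allclose(ks.v_raw, 0.0)

    def test_uniform_motion_speed(self):
        # 1 px/frame at 100 fps and 0.1 mm/px -> 10 mm/s
        ks = K.derive_series(straight_track(step_px=1.0))
        assert np.allclose(ks.v_raw, 10.0)

    def test_unwrap_through_the_pi_cut(self):
        # heading rotating 5 deg/frame through +/-180: unwrapped theta is
        # strictly monotone with constant increments
        frames = []
        for i in range(80):
            ang = np.deg2rad(150 + 5 * i)
            d = np.array([np.cos(ang), -np.sin(ang)])
            S = np.array([(-j) * 5 * d for j in range(10)])[::-1] + 100
            frames.append(fg.FrameMidline(i, C=S.mean(0), S=S, head=S[-1] + 5 * d))
        ks = K.derive_series(fg.TrackSeries(fps=100, mm_per_px=0.5, frames=frames))
        inc = np.diff(ks.theta)
        assert np.all(inc > 0)
        assert np.allclose(inc, np.deg2rad(5), atol=1e-6)

    def test_alpha_left_positive_for_left_bend(self):
        shape = fg.FishShapeSpec()
        pose = fg.PoseSpec(position=(0, 0), heading=0.0,
                           bend_amplitude=np.deg2rad(25))
        ml, _ = fg.midline_polyline(shape, pose)
        from fishgait.geometry import resample_polyline

        S = resample_polyline(ml, np.arange(10) / 10)
        fm = fg.FrameMidline(0, C=ml.mean(0), S=S, head=ml[-1])
        fm2 = fm.copy()
        fm2.frame_index = 1
        track = fg.TrackSeries(fps=100, mm_per_px=0.5, frames=[fm, fm2])
        ks = K.derive_series(track)
        # the caudal tangent is estimated from the S1->S2 chord of the
        # uniformly curved distal arc, which subtends d_s = 0.1 of the body
        # over a bent region of length b: the chord reads the tangent at
        # the chord midpoint, shaving amp * d_s / (2 b) off the angle
        expected = np.deg2rad(25) * (1 - 0.1 / (2 * pose.bend_onset))
        assert ks.alpha[0] > 0  # left bend is positive
        assert ks.alpha[0] == pytest.approx(expected, abs=np.deg2rad(1.0))


class TestBendPosition:
    def test_nine_point_flexed_at_seventh_from_tail(self):
        # collinear from the head through the 7th point from the tail, with
        # the distal chain rigidly rotated 40 deg about that point:
        # k = 6/8 exactly on equidistant points
        pts = np.column_stack([np.arange(9.0), np.zeros(9)])  # tail at x=0
        ang = np.deg2rad(40)
        for i in range(6):  # deflect everything distal to the pivot at x=6
            r = 6.0 - i
            pts[i] = (6.0 - r * np.cos(ang), r * np.sin(ang))
        k = K.bend_position(pts)
        assert k == pytest.approx(6 / 8, abs=1e-9)

    def test_ten_point_flexed_at_second_from_tail(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10)])
        ang = np.deg2rad(35)
        pts[0] = (1 - np.cos(ang), np.sin(ang))
        k = K.bend_position(pts)
        assert k == pytest.approx(1 / 9, abs=1e-9)

    def test_straight_midline_undefined(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10)])
        assert np.isnan(K.bend_position(pts))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            K.bend_position(np.array([[0.0, 0.0], [1.0, 0.0]]))


class TestDetectBends:
    def _series(self, alpha, fps=100.0):
        n = len(alpha)
        return K.KinematicSeries(
            t=np.arange(n) / fps, v=np.zeros(n), v_raw=np.zeros(n),
            theta=np.zeros(n), alpha=np.asarray(alpha, float),
            k=np.full(n, np.nan), fps=fps, mm_per_px=1.0,
            quality=np.ones(n, bool),
        )

    def test_half_sine_is_two_bends_left_then_right(self):
        t = np.linspace(0, np.pi, 21)
        alpha = np.deg2rad(20) * np.sin(t)
        pad = np.zeros(10)
        bends = K.detect_bends(self._series(np.r_[pad, alpha, pad]))
        assert len(bends) == 2
        assert bends[0].direction == "left"
        assert bends[1].direction == "right"
        assert bends[0].delta_alpha == pytest.approx(np.deg2rad(20), rel=1e-6)
        assert bends[1].delta_alpha == pytest.approx(-np.deg2rad(20), rel=1e-6)

    def test_subthreshold_noise_yields_no_bends(self):
        rng = np.random.default_rng(0)
        alpha = rng.normal(0, np.deg2rad(0.8), 300)
        assert K.detect_bends(self._series(alpha)) == []

    def test_scripted_bends_recovered(self):
        script = fg.SwimScript(
            duration=2.0,
            events=[fg.StepEvent(start=0.4, n_bends=3, frequency=12.0,
                                 peak_bend=np.deg2rad(30))],
        )
        sim = fg.simulate_kinematics(script)
        bends = K.detect_bends(series_from_sim(sim))
        assert len(bends) == 3
        for b, (_, row) in zip(bends, sim.bends.iterrows()):
            assert b.delta_alpha == pytest.approx(row.delta_alpha, rel=0.10)


class TestDetectTurnsAndAccels:
    def test_single_ramp_turn(self):
        n, fps = 200, 100.0
        theta = np.zeros(n)
        theta[50:60] = np.linspace(0, np.deg2rad(-30), 10)
        theta[60:] = np.deg2rad(-30)
        ks = K.KinematicSeries(
            t=np.arange(n) / fps, v=np.zeros(n), v_raw=np.zeros(n),
            theta=theta, alpha=np.zeros(n), k=np.full(n, np.nan),
            fps=fps, mm_per_px=1.0, quality=np.ones(n, bool),
        )
        turns = K.detect_turns(ks)
        assert len(turns) == 1
        assert turns[0].turn_angle == pytest.approx(np.deg2rad(-30), rel=1e-6)
        assert turns[0].direction == "right"
        assert turns[0].duration == pytest.approx(0.1, abs=0.02)

    def test_constant_orientation_no_turns(self):
        n = 100
        ks = K.KinematicSeries(
            t=np.arange(n) / 100, v=np.zeros(n), v_raw=np.zeros(n),
            theta=np.full(n, 1.0), alpha=np.zeros(n), k=np.full(n, np.nan),
            fps=100, mm_per_px=1.0, quality=np.ones(n, bool),
        )
        assert K.detect_turns(ks) == []

    def test_scripted_turns_recovered(self):
        script = fg.random_swim_script(2, duration=8.0, turn_prob=1.0)
        sim = fg.simulate_kinematics(script)
        turns = K.detect_turns(series_from_sim(sim))
        assert len(turns) == len(sim.turns)
        for t, (_, row) in zip(turns, sim.turns.iterrows()):
            assert t.turn_angle == pytest.approx(row.turn_angle, rel=0.10)

    def test_speed_rise_detected_with_change(self):
        n, fps = 300, 100.0
        v = np.zeros(n)
        v[100:105] = np.linspace(0, 50, 5)
        v[105:] = 50 * np.exp(-np.arange(n - 105) / 30)
        ks = K.KinematicSeries(
            t=np.arange(n) / fps, v=v, v_raw=v, theta=np.zeros(n),
            alpha=np.zeros(n), k=np.full(n, np.nan), fps=fps,
            mm_per_px=1.0, quality=np.ones(n, bool),
        )
        accels = K.detect_accels(ks)
        assert len(accels) == 1
        assert accels[0].speed_change == pytest.approx(50, rel=0.05)

    def test_constant_speed_no_accels(self):
        n = 100
        ks = K.KinematicSeries(
            t=np.arange(n) / 100, v=np.full(n, 20.0), v_raw=np.full(n, 20.0),
            theta=np.zeros(n), alpha=np.zeros(n), k=np.full(n, np.nan),
            fps=100, mm_per_px=1.0, quality=np.ones(n, bool),
        )
        assert K.detect_accels(ks) == []

    def test_burst_coast_episode_count_matches_steps(self):
        script = fg.random_swim_script(6, duration=8.0)
        sim = fg.simulate_kinematics(script)
        accels = K.detect_accels(series_from_sim(sim))
        assert len(accels) == len(sim.steps)


class TestAssembleSteps:
    def test_bend_pair_with_turn_and_accel_is_one_step(self):
        # one left bend + obligatory right return bend, one turn, one
        # acceleration, then a glide: exactly one step with 2 bends
        ev = fg.StepEvent(start=0.3, n_bends=2, frequency=12.0,
                          turn_angle=np.deg2rad(25), speed_gain=60.0)
        script = fg.SwimScript(duration=1.5, events=[ev])
        sim = fg.simulate_kinematics(script)
        ks = series_from_sim(sim)
        steps = K.assemble_steps(
            K.detect_bends(ks), K.detect_turns(ks), K.detect_accels(ks), ks
        )
        assert len(steps) == 1
        st = steps[0]
        assert st.metrics["n_bends"] == 2
        assert st.turn is not None and st.accel is not None

    def test_widely_separated_bend_pairs_are_two_steps(self):
        events = [fg.StepEvent(start=0.3), fg.StepEvent(start=2.5)]
        script = fg.SwimScript(duration=4.0, events=events)
        sim = fg.simulate_kinematics(script)
        ks = series_from_sim(sim)
        steps = K.assemble_steps(
            K.detect_bends(ks), K.detect_turns(ks), K.detect_accels(ks), ks
        )
        assert len(steps) == 2

    def test_coast_percent_is_the_ratio(self):
        ev = fg.StepEvent(start=0.3, n_bends=3, frequency=10.0, coast_frac=0.6)
        script = fg.SwimScript(duration=2.0, events=[ev])
        sim = fg.simulate_kinematics(script)
        ks = series_from_sim(sim)
        steps = K.assemble_steps(
            K.detect_bends(ks), K.detect_turns(ks), K.detect_accels(ks), ks
        )
        m = steps[0].metrics
        assert m["coast_percent"] == pytest.approx(
            m["coast_duration"] / m["step_duration"]
        )
        assert 0.0 <= m["coast_percent"] <= 1.0
        assert m["bend_duration_total"] <= m["step_duration"] + 1e-9

    def test_step_lengths_bounded_by_total_distance(self):
        script = fg.random_swim_script(9, duration=8.0)
        sim = fg.simulate_kinematics(script)
        ks = series_from_sim(sim)
        steps = K.assemble_steps(
            K.detect_bends(ks), K.detect_turns(ks), K.detect_accels(ks), ks
        )
        total = np.trapezoid(ks.v, ks.t)
        assert sum(s.metrics["step_length"] for s in steps) <= total + 1e-6


class TestMirrorSymmetry:
    def test_mirroring_negates_angles_and_swaps_labels(self):
        script = fg.random_swim_script(13, duration=6.0, turn_prob=1.0)
        track, _ = fg.synth.synthetic_track(script)
        mirrored = track.copy()
        for fm in mirrored.frames:  # reflect about a horizontal axis
            fm.C[1] = -fm.C[1]
            fm.S[:, 1] = -fm.S[:, 1]
            fm.head[1] = -fm.head[1]
        p = K.GaitParams()
        ks, ksm = K.derive_series(track, p), K.derive_series(mirrored, p)
        assert np.allclose(ksm.alpha, -ks.alpha, atol=1e-9)
        assert np.allclose(np.diff(ksm.theta), -np.diff(ks.theta), atol=1e-9)
        assert np.allclose(ksm.v_raw, ks.v_raw)
        b, bm = K.detect_bends(ks, p), K.detect_bends(ksm, p)
        assert [x.direction for x in bm] == [
            {"left": "right", "right": "left"}[x.direction] for x in b
        ]
        assert [abs(x.delta_alpha) for x in bm] == pytest.approx(
            [abs(x.delta_alpha) for x in b]
        )


class TestMacroSummary:
    def _ks(self, v, theta=None, fps=100.0):
        n = len(v)
        return K.KinematicSeries(
            t=np.arange(n) / fps, v=np.asarray(v, float),
            v_raw=np.asarray(v, float),
            theta=np.zeros(n) if theta is None else theta,
            alpha=np.zeros(n), k=np.full(n, np.nan),
            fps=fps, mm_per_px=1.0, quality=np.ones(n, bool),
        )

    def test_stationary_minute_is_all_freezing(self):
        ks = self._ks(np.zeros(6000))
        m = K.macro_summary(ks, [], [], [])
        assert m["freezing_s"] == pytest.approx(60.0)
        assert m["distance_mm"] == 0.0
        assert m["step_count"] == 0

    def test_circular_swim_closed_form(self):
        # constant speed s on a circle of radius r for T seconds:
        # distance = s T and meandering = s / r rad/s
        fps, T = 100.0, 20.0
        s_mm, r_mm = 30.0, 40.0
        n = int(T * fps)
        omega = s_mm / r_mm  # rad/s
        theta = omega * np.arange(n) / fps
        ks = self._ks(np.full(n, s_mm), theta=theta, fps=fps)
        turns = K.detect_turns(ks)
        m = K.macro_summary(ks, [], turns, [])
        assert m["distance_mm"] == pytest.approx(s_mm * T, rel=0.01)
        assert m["meandering_rad_s"] == pytest.approx(omega, rel=0.05)

    def test_left_only_turns_have_zero_right_totals(self):
        script = fg.random_swim_script(3, duration=6.0, turn_prob=1.0)
        for ev in script.events:
            ev.turn_angle = abs(ev.turn_angle)
        sim = fg.simulate_kinematics(script)
        ks = series_from_sim(sim)
        bends = K.detect_bends(ks)
        turns = K.detect_turns(ks)
        steps = K.assemble_steps(bends, turns, K.detect_accels(ks), ks)
        m = K.macro_summary(ks, bends, turns, steps)
        assert m["turn_count_right"] == 0
        assert m["total_turn_angle_right"] == 0.0
        assert m["turn_count_left"] == len(turns)

    def test_left_right_splits_sum_to_totals(self):
        script = fg.random_swim_script(17, duration=8.0, turn_prob=0.8)
        sim = fg.simulate_kinematics(script)
        ks = series_from_sim(sim)
        bends, turns = K.detect_bends(ks), K.detect_turns(ks)
        steps = K.assemble_steps(bends, turns, K.detect_accels(ks), ks)
        m = K.macro_summary(ks, bends, turns, steps)
        assert m["turn_count_left"] + m["turn_count_right"] == m["turn_count"]
        assert m["total_turn_angle_left"] + m["total_turn_angle_right"] == (
            pytest.approx(m["total_turn_angle_rad"])
        )
        assert m["bend_count_left"] + m["bend_count_right"] == m["bend_count"]

    def test_thigmotaxis_counts_wall_proximity(self):
        n = 200
        ks = self._ks(np.full(n, 10.0))
        # square arena 100x100 px at 1 mm/px; path hugs the left wall for
        # the first half, then sits in the center
        c = np.tile([50.0, 50.0], (n, 1))
        c[: n // 2, 0] = 2.0
        poly = np.array([[0, 0], [100, 0], [100, 100], [0, 100]])
        m = K.macro_summary(ks, [], [], [], arena_polygon=poly,
                            wall_band_mm=10.0, centroid_px=c)
        assert m["thigmotaxis_s"] == pytest.approx(n / 2 / 100.0)


class TestGaitRecovery:
    def test_scripted_steps_recovered_across_seeds(self):
        # condensed version of the full recovery study: step counts exact,
        # per-script mean bend-wave-frequency error within 5%, turn angles
        # within 10%
        for seed in range(6):
            script = fg.random_swim_script(seed, duration=8.0)
            sim = fg.simulate_kinematics(script)
            ks = series_from_sim(sim)
            p = K.GaitParams()
            steps = K.assemble_steps(
                K.detect_bends(ks, p), K.detect_turns(ks, p),
                K.detect_accels(ks, p), ks, p,
            )
            assert len(steps) == len(sim.steps)
            errs = [
                abs(s.metrics["bend_wave_frequency"] - row.bend_wave_frequency)
                / row.bend_wave_frequency
                for s, (_, row) in zip(steps, sim.steps.iterrows())
            ]
            assert np.mean(errs) <= 0.05
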