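"""Gaze pipeline: blinks, epochs, spread, projection, saccades, subgoals."""

import warnings

import numpy as np
import pandas as pd
import pytest

from navgaze.arena import build_arena
from navgaze.gaze import (detect_saccades, detect_subgoals,
                          filter_blinks, find_alternative_trajectories,
                          gaze_on_alternative_flags, gaze_spread,
                          goal_gaze_stats, moving_average,
                          normalize_trial_time, project_gaze_on_trajectory,
                          segment_epochs)
from navgaze.planning import Trajectory, optimal_path, value_iteration
from navgaze.session import SessionLog, TrialRecord


def _make_log(n, joy=None, openness=None, frame_rate=90.0):
    frames = pd.DataFrame({
        "t": np.arange(n) / frame_rate,
        "pos_x": np.zeros(n), "pos_y": np.zeros(n),
        "heading_deg": np.zeros(n),
        "joy_speed": np.zeros(n) if joy is None else joy,
        "gaze_x": np.zeros(n), "gaze_y": np.zeros(n),
        "gdir_x": np.zeros(n), "gdir_y": np.ones(n), "gdir_z": np.zeros(n),
        "pupil_open": np.ones(n) if openness is None else openness,
    })
    return SessionLog(frames, frame_rate)


class TestFilterBlinks:
    def test_all_open_session_unchanged(self):
        log = filter_blinks(_make_log(100))
        assert log.frames["gaze_valid"].all()

    def test_fully_closed_warns_and_masks_everything(self):
        with pytest.warns(UserWarning, match="blink"):
            log = filter_blinks(_make_log(50, openness=np.zeros(50)))
        assert not log.frames["gaze_valid"].any()

    def test_synthetic_blinks_masked_exactly(self, synth_session):
        log, _, truth = synth_session
        log = filter_blinks(log)
        for tt in truth.trials:
            fr = log.frames.iloc[tt.frame0: tt.frame0 + tt.n_frames]
            masked = np.flatnonzero(~fr["gaze_valid"].to_numpy())
            assert set(masked.tolist()) == set(tt.blink_frames.tolist())


class TestSegmentEpochs:
    def test_step_profile_onset_near_step(self):
        """Hand-computed moving average: onset within the 5-frame filter delay."""
        joy = np.zeros(300)
        joy[100:250] = 1.0
        log = _make_log(300, joy=joy)
        tr = TrialRecord(0, 0, 1, t_appear=0.0, t_foveate=0.2,
                         t_press=299 / 90.0)
        segment_epochs(log, tr)
        onset_frame = round(tr.t_onset * 90)
        offset_frame = round(tr.t_offset * 90)
        assert abs(onset_frame - 100) <= 5
        assert abs(offset_frame - 249) <= 5
        assert not tr.no_movement

    def test_zero_joystick_flags_no_movement(self):
        log = _make_log(200)
        tr = TrialRecord(0, 0, 1, t_appear=0.0, t_foveate=0.2,
                         t_press=199 / 90.0)
        segment_epochs(log, tr)
        assert tr.no_movement
        assert np.isnan(tr.t_onset)

    def test_generator_onset_offset_within_three_frames(self, synth_session):
        log, trials, truth = synth_session
        log = filter_blinks(log)
        for tr, tt in zip(trials, truth.trials):
            rec = segment_epochs(log, tr)
            assert abs(rec.t_onset - tt.t_onset) * 90 <= 3
            assert abs(rec.t_offset - tt.t_offset) * 90 <= 3

    def test_epoch_durations_partition_the_trial(self, synth_session):
        log, trials, _ = synth_session
        log = filter_blinks(log)
        for tr in trials:
            segment_epochs(log, tr)
            total = tr.t_press - tr.t_appear
            parts = ((tr.t_foveate - tr.t_appear)
                     + (tr.t_onset - tr.t_foveate)
                     + (tr.t_offset - tr.t_onset))
            post = tr.t_press - tr.t_offset
            assert parts + post == pytest.approx(total, abs=1e-9)
            assert post >= 0


class TestGazeSpread:
    @staticmethod
    def _log_from_gaze(per_trial_gaze, frame_rate=90.0):
        chunks, trials = [], []
        t0 = 0.0
        for i, g in enumerate(per_trial_gaze):
            n = len(g)
            t = t0 + np.arange(n) / frame_rate
            chunks.append(pd.DataFrame({
                "t": t, "pos_x": 0.0, "pos_y": 0.0, "heading_deg": 0.0,
                "joy_speed": 1.0, "gaze_x": g[:, 0], "gaze_y": g[:, 1],
                "gdir_x": 0.0, "gdir_y": 1.0, "gdir_z": 0.0,
                "pupil_open": 1.0,
            }))
            trials.append(TrialRecord(i, 0, 1, t_appear=t[0], t_foveate=t[0],
                                      t_onset=t[0], t_offset=t[-1],
                                      t_press=t[-1]))
            t0 = t[-1] + 1.0 / frame_rate
        return SessionLog(pd.concat(chunks, ignore_index=True)), trials

    def test_constant_within_variable_across(self):
        gaze = [np.full((50, 2), float(i)) for i in range(5)]
        log, trials = self._log_from_gaze(gaze)
        out = gaze_spread(log, trials, "movement")
        assert out["within_m"] == 0.0
        assert out["across_m"] > 0.0

    def test_iid_normal_closed_form(self):
        """x, y ~ N(0,1): within-spread ~ sqrt(2), across ~ sqrt(2/T)."""
        rng = np.random.default_rng(0)
        T = 500
        gaze = [rng.normal(size=(T, 2)) for _ in range(200)]
        log, trials = self._log_from_gaze(gaze)
        out = gaze_spread(log, trials, "movement")
        assert out["within_m"] == pytest.approx(np.sqrt(2.0), rel=0.02)
        assert out["across_m"] == pytest.approx(np.sqrt(2.0 / T), rel=0.15)

    def test_duplicating_trials_preserves_within_spread(self):
        rng = np.random.default_rng(1)
        gaze = [rng.normal(size=(60, 2)) for _ in range(4)]
        log1, t1 = self._log_from_gaze(gaze)
        log2, t2 = self._log_from_gaze(gaze + gaze)
        s1 = gaze_spread(log1, t1, "movement")
        s2 = gaze_spread(log2, t2, "movement")
        assert s1["within_m"] == pytest.approx(s2["within_m"], rel=1e-12)

    def test_too_few_trials_rejected(self):
        log, trials = self._log_from_gaze([np.zeros((10, 2))])
        with pytest.raises(ValueError):
            gaze_spread(log, trials, "movement")


class TestGoalGazeStats:
    def test_pinned_at_goal_center(self, arena3, synth_session):
        log, trials, _ = synth_session
        log = filter_blinks(log)
        tr = trials[0]
        segment_epochs(log, tr)
        log2 = log.copy()
        center = arena3.centroids_m[tr.goal]
        fr = log2.trial_frames(tr)
        log2.frames.loc[fr.index, "gaze_x"] = center[0]
        log2.frames.loc[fr.index, "gaze_y"] = center[1]
        out = goal_gaze_stats(log2, tr, arena3, "movement")
        assert out["fraction_near"] == 1.0
        assert out["mean_distance_m"] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_distance(self, arena3, synth_session):
        log, trials, _ = synth_session
        log = filter_blinks(log)
        tr = trials[1]
        segment_epochs(log, tr)
        log2 = log.copy()
        center = arena3.centroids_m[tr.goal]
        fr = log2.trial_frames(tr)
        log2.frames.loc[fr.index, "gaze_x"] = center[0] + 10.0
        log2.frames.loc[fr.index, "gaze_y"] = center[1]
        out = goal_gaze_stats(log2, tr, arena3, "movement")
        assert out["fraction_near"] == 0.0
        assert out["mean_distance_m"] == pytest.approx(10.0)

    def test_mixture_fraction_matches_generator_contract(self, arena3):
        """60% goal-fixation weight yields the labeled near-goal fraction."""
        from navgaze.synth import SynthConfig, generate_session
        mix = {"goal": 0.6, "relevant": 0.0, "alternative": 0.0,
               "random": 0.4, "sweep": 0.0}
        cfg = SynthConfig(arena=arena3, n_trials=60, seed=9, mixture=mix,
                          gaze_noise_deg=0.0, gaze_jitter_deg=0.0,
                          n_backward_sweeps=0, n_forward_sweeps=0,
                          use_relevance_targets=False)
        log, trials, truth = generate_session(cfg)
        log = filter_blinks(log)
        near_frames = total = 0
        expect = 0
        for tr, tt in zip(trials, truth.trials):
            segment_epochs(log, tr)
            for epoch in ("pre-movement", "movement"):
                fr = log.trial_frames(tr, epoch)
                fr = fr[fr["gaze_valid"]]
                d = np.linalg.norm(
                    fr[["gaze_x", "gaze_y"]].to_numpy()
                    - arena3.centroids_m[tr.goal], axis=1)
                near_frames += (d <= 2.0).sum()
                total += len(fr)
                idx = fr.index.to_numpy() - tt.frame0
                expect += (tt.fixation[idx] == "goal").sum()
        got = near_frames / total
        labeled = expect / total
        assert got == pytest.approx(labeled, abs=0.03 + 0.05 * (1 - labeled))

    def test_empty_epoch_reported_missing(self, arena3, synth_session):
        log, trials, _ = synth_session
        tr = trials[0]
        log2 = filter_blinks(log).copy()
        fr = log2.trial_frames(tr)
        log2.frames.loc[fr.index, "gaze_valid"] = False
        out = goal_gaze_stats(log2, tr, arena3, "movement")
        assert np.isnan(out["fraction_near"]) and out["n_frames"] == 0


class TestProjection:
    traj = Trajectory([0, 1], np.array([[0.0, 0.0], [10.0, 0.0]]), 10.0)

    def test_endpoints(self):
        f, valid = project_gaze_on_trajectory(
            np.array([[0.0, 0.1], [10.0, -0.1]]), self.traj)
        assert valid.all()
        assert f[0] == pytest.approx(0.0, abs=0.02)
        assert f[1] == pytest.approx(1.0, abs=0.02)

    def test_constant_speed_gaze_is_linear_in_time(self):
        t = np.linspace(0, 1, 200)
        gaze = np.column_stack([10 * t, 0.3 * np.ones_like(t)])
        f, valid = project_gaze_on_trajectory(gaze, self.traj)
        assert valid.all()
        resid = f - np.polyval(np.polyfit(t, f, 1), t)
        r2 = 1 - resid.var() / f.var()
        assert r2 > 0.999

    def test_far_gaze_fully_masked(self):
        gaze = np.full((50, 2), [5.0, 5.0])
        f, valid = project_gaze_on_trajectory(gaze, self.traj)
        assert not valid.any()
        assert np.isnan(f).all()

    def test_zero_length_rejected(self):
        bad = Trajectory([0], np.array([[0.0, 0.0]]), 0.0)
        with pytest.raises(ValueError):
            project_gaze_on_trajectory(np.zeros((3, 2)), bad)

    def test_invariant_to_uniform_rescale(self):
        rng = np.random.default_rng(2)
        gaze = rng.uniform(-1, 11, size=(100, 2))
        f1, v1 = project_gaze_on_trajectory(gaze, self.traj)
        big = Trajectory([0, 1], self.traj.polyline * 7.0, 70.0)
        f2, v2 = project_gaze_on_trajectory(gaze * 7.0, big, radius_m=14.0)
        assert np.allclose(f1[v1], f2[v1], atol=1e-12)


class TestSaccades:
    def test_constant_direction_no_saccades(self):
        gdir = np.tile([0.0, 1.0, 0.0], (100, 1))
        angles, onsets = detect_saccades(gdir, 90.0)
        assert len(onsets) == 0
        assert np.nanmax(angles.speed) == 0.0

    def test_single_step_gives_one_onset(self):
        """A 3-frame, ~200 deg/s excursion crosses 50 deg/s exactly once."""
        az = np.zeros(60)
        az[30:33] = [2.2, 4.4, 6.6]  # ~200 deg/s for 3 frames at 90 Hz
        az[33:] = 6.6
        rad = np.radians(az)
        gdir = np.column_stack([np.sin(rad), np.cos(rad), np.zeros(60)])
        _, onsets = detect_saccades(gdir, 90.0)
        assert len(onsets) == 1
        assert onsets[0] == 30

    @pytest.mark.parametrize("omega", [20.0, 45.0])
    def test_pure_azimuthal_rotation_speed(self, omega):
        t = np.arange(200) / 90.0
        rad = np.radians(omega * t)
        gdir = np.column_stack([np.sin(rad), np.cos(rad), np.zeros_like(rad)])
        angles, _ = detect_saccades(gdir, 90.0)
        assert np.nanmedian(angles.speed) == pytest.approx(omega, rel=0.01)

    def test_zero_norm_frames_masked(self):
        gdir = np.tile([0.0, 1.0, 0.0], (10, 1))
        gdir[4] = 0.0
        angles, _ = detect_saccades(gdir, 90.0)
        assert not angles.valid[4]
        assert np.isnan(angles.azimuth[4])

    def test_invariant_to_vector_norm_scaling(self):
        rng = np.random.default_rng(3)
        gdir = rng.normal(size=(300, 3))
        _, on1 = detect_saccades(gdir, 90.0)
        scale = rng.uniform(0.5, 3.0, size=(300, 1))
        _, on2 = detect_saccades(gdir * scale, 90.0)
        assert np.array_equal(on1, on2)


class TestSubgoals:
    def test_straight_heading_no_turns(self):
        assert detect_subgoals(np.full(200, 33.0), 90.0) == []

    def test_synthetic_turn_detected_and_spans_rotation(self):
        """90 deg over 0.5 s peaks at 180 deg/s, above the 60 deg/s threshold."""
        h = np.concatenate([np.zeros(100),
                            np.linspace(0, 90, 45),
                            np.full(100, 90.0)])
        turns = detect_subgoals(h, 90.0)
        assert len(turns) == 1
        assert turns[0]["start"] >= 90 and turns[0]["end"] <= 155
        assert turns[0]["subgoal"] == 1

    def test_l_shaped_movement_numbers_subgoals_from_goal(self, synth_session):
        log, trials, truth = synth_session
        found = False
        for tr, tt in zip(trials, truth.trials):
            if len(tt.trajectory.states) < 3:
                continue
            fr = log.trial_frames(tr, "movement")
            if len(fr) < 10:
                continue
            turns = detect_subgoals(fr["heading_deg"].to_numpy(), 90.0,
                                    fr[["pos_x", "pos_y"]].to_numpy())
            if not turns:
                continue
            found = True
            # numbering counts back from the goal: last turn is subgoal 1
            assert turns[-1]["subgoal"] == 1
            assert [t["subgoal"] for t in turns] == list(
                range(len(turns), 0, -1))
        assert found

    def test_invariant_to_heading_offset(self):
        rng = np.random.default_rng(4)
        h = np.cumsum(rng.normal(0, 1.5, size=400))
        t1 = detect_subgoals(h, 90.0)
        t2 = detect_subgoals((h + 213.7) % 360.0, 90.0)
        assert [(t["start"], t["end"]) for t in t1] == \
            [(t["start"], t["end"]) for t in t2]


class TestNormalizeTrialTime:
    def test_two_turn_worked_indexing(self):
        """Two turns: indices -350..-1 with turns at -250..-226 and -125..-101."""
        x = np.arange(500.0)
        turns = [{"start": 150, "end": 200}, {"start": 320, "end": 360}]
        idx, vals = normalize_trial_time(x, turns)
        assert idx[0] == -350 and idx[-1] == -1
        assert len(vals) == 350
        # turn blocks occupy -125..-101 (last) and -250..-226 (second last)
        turn1 = vals[(idx >= -125) & (idx <= -101)]
        assert turn1.min() >= 320 and turn1.max() <= 360
        turn2 = vals[(idx >= -250) & (idx <= -226)]
        assert turn2.min() >= 150 and turn2.max() <= 200

    def test_zero_turn_trial_single_segment(self):
        idx, vals = normalize_trial_time(np.linspace(0, 1, 77), [])
        assert len(vals) == 100
        assert idx[0] == -100
        assert vals[0] == 0.0 and vals[-1] == 1.0

    def test_constant_series_identity(self):
        idx, vals = normalize_trial_time(np.full(120, 3.14),
                                         [{"start": 40, "end": 60}])
        assert np.allclose(vals, 3.14)

    def test_overlapping_turns_merged_with_warning(self):
        with pytest.warns(UserWarning, match="merged"):
            idx, vals = normalize_trial_time(
                np.arange(100.0),
                [{"start": 10, "end": 30}, {"start": 25, "end": 40}])
        assert len(vals) == 2 * 100 + 25  # one merged turn


class TestAlternatives:
    def test_open_arena_short_hop_single_class(self):
        """All near-optimal paths between neighbors overlap: one class."""
        arena = build_arena(3, 2.0)
        goal = int(np.flatnonzero(arena.adjacency[20])[0])
        alts = find_alternative_trajectories(arena, 20, goal)
        assert len(alts) == 1

    def test_retained_paths_pairwise_distinct(self):
        """Across the open arena, retained paths share at most half their states."""
        arena = build_arena(3, 2.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alts = find_alternative_trajectories(arena, 0, arena.n_cells - 1)
        assert len(alts) >= 1
        vf = value_iteration(arena, arena.n_cells - 1)
        limit = 1.25 * (-vf.values[0]) * arena.side_length
        for i, a in enumerate(alts):
            assert a.length_m <= limit + 1e-9
            for b in alts[i + 1:]:
                shared = len(set(a.states) & set(b.states))
                assert shared <= 0.5 * min(len(a.states), len(b.states))

    def test_two_corridor_arena_two_alternatives(self):
        """Symmetric double corridor: exactly two retained path classes."""
        base = build_arena(3, 2.0)
        cut = 0.5
        crossing = [
            e.k for e in base.edges
            if e.interior
            and (base.centroids_m[e.cells[0]][0] - cut)
            * (base.centroids_m[e.cells[1]][0] - cut) < 0
        ]
        # keep only the extreme top and bottom crossings open
        ys = {k: base.edges[k].midpoint[1] for k in crossing}
        keep = {min(ys, key=ys.get), max(ys, key=ys.get)}
        arena = build_arena(3, 2.0, obstacles=[k for k in crossing
                                               if k not in keep])
        assert arena.is_connected()
        # start west of the cut, goal east, both mid-height
        cents = arena.centroids_m
        s0 = int(np.argmin(np.abs(cents[:, 1]) + np.abs(cents[:, 0] + 4)))
        goal = int(np.argmin(np.abs(cents[:, 1]) + np.abs(cents[:, 0] - 4)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alts = find_alternative_trajectories(arena, s0, goal)
        assert len(alts) == 2

    def test_gaze_on_executed_path_never_flags_alternative(self, arena3):
        vf = value_iteration(arena3, goal=50)
        executed = optimal_path(arena3, vf, 2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alts = find_alternative_trajectories(arena3, 2, 50)
        gaze = executed.polyline[
            np.linspace(0, len(executed.polyline) - 1, 40).astype(int)
        ]
        flags = gaze_on_alternative_flags(gaze, executed, alts, arena3)
        assert not flags.any()


def test_moving_average_edge_truncated():
    x = np.arange(10.0)
    out = moving_average(x, 5)
    assert out[0] == pytest.approx(np.mean(x[:3]))  # truncated window
    assert out[5] == pytest.approx(np.mean(x[3:8]))
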