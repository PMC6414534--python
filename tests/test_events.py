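import numpy as np
import pytest

from gazecross.events import (
    InsufficientDataError,
    ParserParams,
    candidate_smooth_segments,
    compute_velocity,
    extract_saccades,
    parse_trial,
    pursuit_score,
    qc_filter,
    sample_labels,
    summarize_events,
)
from gazecross.simulate import ScanpathScript, ScriptEvent, random_script, simulate_scanpath, DEFAULT_COHORT

from conftest import make_recording
import oracles

PARAMS = ParserParams()
RAW = ParserParams(vel_window_ms=0.5)  # effectively unsmoothed


class TestVelocity:
    def test_constant_position_zero_speed(self, geometry):
        rec = make_recording(np.full(1000, 960.0), np.full(1000, 540.0))
        tr = compute_velocity(rec, geometry, PARAMS)
        np.testing.assert_allclose(tr.speed, 0.0, atol=1e-12)

    def test_linear_motion_closed_form(self, geometry):
        # 1 px/ms horizontal: speed = centre deg/px factor * 1000
        rec = make_recording(np.arange(500, 1500, 1.0), np.full(1000, 540.0))
        tr = compute_velocity(rec, geometry, PARAMS)
        kx, _ = oracles.deg_per_px_centre(geometry)
        np.testing.assert_allclose(tr.speed, kx * 1000.0, rtol=1e-9)

    def test_step_peak_closed_form(self, geometry):
        # sustained 5 px step: central difference spreads it over 2 ms
        x = np.concatenate([np.full(50, 100.0), np.full(50, 105.0)])
        rec = make_recording(x, np.full(100, 540.0))
        tr = compute_velocity(rec, geometry, RAW)
        kx, _ = oracles.deg_per_px_centre(geometry)
        assert tr.speed.max() == pytest.approx(2.5 * kx * 1000.0, rel=1e-9)

    def test_matches_reference_loop(self, geometry, rng):
        script = random_script(rng, DEFAULT_COHORT.groups[1], duration_ms=2000.0)
        rec, _ = simulate_scanpath(script, geometry, seed=3)
        tr = compute_velocity(rec, geometry, PARAMS)
        ref = oracles.reference_speeds(rec, geometry, PARAMS.vel_window_ms)
        ok = np.isfinite(tr.speed) & np.isfinite(ref)
        np.testing.assert_allclose(tr.speed[ok], ref[ok], rtol=1e-8)

    def test_insufficient_samples(self, geometry):
        rec = make_recording([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], valid=[True, False, True])
        with pytest.raises(InsufficientDataError):
            compute_velocity(rec, geometry, PARAMS)

    def test_undefined_near_invalid(self, geometry):
        valid = np.ones(100, bool)
        valid[40:45] = False
        rec = make_recording(np.arange(100.0) + 500, np.full(100, 540.0), valid=valid)
        tr = compute_velocity(rec, geometry, PARAMS)
        assert np.all(np.isnan(tr.speed[40:45]))


class TestSaccadeExtraction:
    def _trace(self, speeds, geometry):
        # build a recording whose per-sample x-velocity produces `speeds` deg/s
        kx, _ = oracles.deg_per_px_centre(geometry)
        v_px = np.asarray(speeds) / (kx * 1000.0)
        x = 200 + np.concatenate([[0.0], np.cumsum(v_px)])[:-1]
        rec = make_recording(x, np.full(len(x), 540.0))
        return compute_velocity(rec, geometry, RAW)

    def test_all_subthreshold_empty(self, geometry):
        tr = self._trace(np.full(300, 20.0), geometry)
        assert extract_saccades(tr, PARAMS) == []

    def test_single_burst_matches_per_sample_oracle(self, geometry):
        speeds = np.full(300, 5.0)
        speeds[100:130] = 300.0
        tr = self._trace(speeds, geometry)
        segs = extract_saccades(tr, PARAMS)
        oracle = np.flatnonzero(tr.speed > PARAMS.saccade_vel_thresh)
        assert len(segs) == 1
        a, b = segs[0]
        assert (a, b) == (oracle[0], oracle[-1] + 1)

    def test_two_bursts(self, geometry):
        speeds = np.full(500, 5.0)
        speeds[100:130] = 300.0
        speeds[330:360] = 300.0
        tr = self._trace(speeds, geometry)
        assert len(extract_saccades(tr, PARAMS)) == 2


class TestSmoothCandidates:
    @staticmethod
    def _trace_of(speeds):
        from gazecross.events import VelocityTrace

        speeds = np.asarray(speeds, float)
        return VelocityTrace(t=np.arange(len(speeds), dtype=float), speed=speeds)

    @pytest.mark.parametrize(
        "dur_ms,expected", [(80, 0), (100, 1), (150, 1)],
        ids=["below-minimum", "exact-minimum-inclusive", "above-minimum"],
    )
    def test_minimum_duration_bound(self, dur_ms, expected):
        # sub-threshold run of dur_ms bounded by saccade bursts
        speeds = np.full(400, 300.0)
        speeds[200 : 200 + dur_ms] = 10.0
        tr = self._trace_of(speeds)
        sacc = extract_saccades(tr, PARAMS)
        cands = candidate_smooth_segments(tr, sacc, PARAMS)
        assert len(cands) == expected
        if expected:
            a, b = cands[0]
            assert (b - a) == dur_ms

    def test_intermediate_band_not_candidate(self):
        # 40 deg/s sits between the pursuit ceiling and the saccade threshold
        tr = self._trace_of(np.full(400, 40.0))
        assert candidate_smooth_segments(tr, extract_saccades(tr, PARAMS), PARAMS) == []


class TestPursuitScore:
    def test_noiseless_ramp_scores_zero(self):
        t = np.arange(500.0)
        x = 200 + 0.4 * t
        y = 300 + 0.1 * t
        assert pursuit_score(t, x, y, PARAMS) == pytest.approx(0.0, abs=1e-20)

    def test_jittered_fixation_matches_direct_formula(self, rng):
        t = np.arange(300.0)
        x = 960 + rng.normal(0, 0.5, 300)
        y = 540 + rng.normal(0, 0.5, 300)
        score = pursuit_score(t, x, y, PARAMS)
        ref = oracles.reference_pursuit_score(t, x, y)
        assert score == pytest.approx(ref, rel=1e-6)
        assert score > 1e-3  # orders of magnitude above the pursuit threshold

    def test_true_pursuit_scores_below_threshold(self, rng):
        # 10 deg/s for 500 ms sweeps ~193 px of arc; exp(A) is astronomical
        t = np.arange(500.0)
        v = 10.0 / 25.912  # px/ms
        x = 300 + v * t + rng.normal(0, 0.5, 500)
        y = 400 + rng.normal(0, 0.5, 500)
        score = pursuit_score(t, x, y, PARAMS)
        ref = oracles.reference_pursuit_score(t, x, y)
        assert score < 1e-9 and ref < 1e-9

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            pursuit_score(np.arange(3.0), np.arange(3.0), np.arange(3.0), PARAMS)


class TestParseTrial:
    def test_pure_fixation(self, geometry):
        script = ScanpathScript([ScriptEvent("fixation", 10_000.0, position=(960, 540))])
        rec, _ = simulate_scanpath(script, geometry, seed=0)
        segs = parse_trial(rec, geometry, PARAMS)
        assert [s.label for s in segs] == ["fixation"]
        assert segs[0].duration == rec.duration_ms

    def test_scripted_trio_boundaries(self, geometry):
        script = ScanpathScript(
            [
                ScriptEvent("fixation", 3000.0, position=(400, 400)),
                ScriptEvent("saccade", 40.0),
                ScriptEvent("pursuit", 6960.0, position=(800, 300), velocity_deg_s=5.0, heading_deg=20.0),
            ]
        )
        rec, _ = simulate_scanpath(script, geometry, seed=1)
        segs = parse_trial(rec, geometry, PARAMS)
        assert [s.label for s in segs] == ["fixation", "saccade", "pursuit"]
        assert segs[0].t_end == pytest.approx(3000.0, abs=10.0)
        assert segs[2].t_start == pytest.approx(3040.0, abs=10.0)

    def test_partition_is_exact(self, geometry, rng):
        for s in range(5):
            script = random_script(np.random.default_rng(s), DEFAULT_COHORT.groups[s % 3])
            rec, _ = simulate_scanpath(script, geometry, seed=s)
            segs = parse_trial(rec, geometry, PARAMS)
            assert sum(seg.duration for seg in segs) == pytest.approx(rec.duration_ms, abs=1e-9)
            for a, b in zip(segs, segs[1:]):
                assert a.t_end == pytest.approx(b.t_start, abs=1e-9)

    def test_determinism(self, geometry):
        script = random_script(np.random.default_rng(9), DEFAULT_COHORT.groups[0])
        rec, _ = simulate_scanpath(script, geometry, seed=9)
        s1 = parse_trial(rec, geometry, PARAMS)
        s2 = parse_trial(rec, geometry, PARAMS)
        assert [(a.label, a.t_start, a.t_end) for a in s1] == [(a.label, a.t_start, a.t_end) for a in s2]

    def test_raising_threshold_never_adds_saccades(self, geometry):
        script = random_script(np.random.default_rng(4), DEFAULT_COHORT.groups[1])
        rec, _ = simulate_scanpath(script, geometry, seed=4)
        counts = []
        for thr in (50.0, 80.0, 150.0, 400.0):
            segs = parse_trial(rec, geometry, ParserParams(saccade_vel_thresh=thr))
            counts.append(sum(1 for s in segs if s.label == "saccade"))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_agrees_with_brute_force_classifier(self, geometry):
        from gazecross.events import compute_velocity

        for s in range(6):
            script = random_script(np.random.default_rng(50 + s), DEFAULT_COHORT.groups[s % 3], duration_ms=2000.0)
            rec, _ = simulate_scanpath(script, geometry, seed=60 + s)
            trace = compute_velocity(rec, geometry, PARAMS)
            lab = sample_labels(rec, trace, PARAMS)
            ref = oracles.reference_labels(rec, geometry, PARAMS)
            assert np.array_equal(lab, ref)


class TestQcFilter:
    def _noisy(self, n_supra_frac, trial_id, geometry):
        # 5 px/ms steps give ~130 deg/s; alternate with still samples
        n = 200
        step = np.zeros(n)
        k = int(n_supra_frac * n)
        step[:k] = 5.0
        x = 300 + np.cumsum(step)
        return make_recording(x, np.full(n, 540.0), trial_id=trial_id)

    def test_majority_rule_and_participant_exclusion(self, geometry):
        good = [self._noisy(0.0, f"g{i}", geometry) for i in range(4)]
        bad = [self._noisy(0.9, f"b{i}", geometry) for i in range(4)]
        trials = {
            "clean": good * 2,
            "noisy": bad[:3] + good[:1] + bad[3:],  # 4 of 5 removed -> excluded
            "borderline": bad[:2] + good[:2],  # exactly half removed -> retained
        }
        kept, removed, excluded = qc_filter(trials, geometry, PARAMS)
        assert excluded == ["noisy"]
        assert "clean" in kept and len(kept["clean"]) == 8
        assert "borderline" in kept and len(kept["borderline"]) == 2
        assert all(pid == "noisy" or pid == "borderline" for pid, _ in removed)


class TestSummaries:
    def test_single_fixation(self):
        from gazecross.io import EventSegment

        segs = [EventSegment("t", "fixation", 0.0, 10_000.0, 1.0, 1.0)]
        s = summarize_events(segs, 10_000.0)
        assert s.counts["fixation"] == 1
        assert s.total_ms["fixation"] == 10_000.0
        assert s.proportions["fixation"] == 1.0

    def test_empty(self):
        s = summarize_events([], 10_000.0)
        assert all(v == 0 for v in s.counts.values())
        assert all(v == 0.0 for v in s.total_ms.values())

    def test_totals_sum_to_trial_duration(self, geometry):
        script = random_script(np.random.default_rng(2), DEFAULT_COHORT.groups[2])
        rec, _ = simulate_scanpath(script, geometry, seed=2)
        segs = parse_trial(rec, geometry, PARAMS)
        s = summarize_events(segs, rec.duration_ms)
        assert sum(s.total_ms.values()) == pytest.approx(rec.duration_ms)
        assert sum(s.total_ms[lab] for lab in s.total_ms) == pytest.approx(
            sum(seg.duration for seg in segs)
        )
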