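import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr, ndtri
from scipy.stats import binomtest

from saccmap import synth
from saccmap.gaze import process_trial, smooth_velocity, detect_saccades
from saccmap.geometry import default_layout
from saccmap.records import Condition


class TestObserverModel:
    def test_gain_field_shape(self, poi):
        obs = synth.default_observers()[Condition.CUE_SOA200]
        assert obs.gain(poi.st) == pytest.approx(2.0, abs=1e-6)
        assert obs.gain(poi.remap) == pytest.approx(1.8, abs=1e-6)
        assert obs.gain((0.0, -9.0)) == pytest.approx(1.0, abs=1e-3)

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError):
            synth.ObserverModel(baseline_gain=0.5,
                                loci=(synth.AttentionLocus((0, 0), -0.7, 2.0),))

    def test_lapse_bounds(self):
        with pytest.raises(ValueError):
            synth.ObserverModel(lapse_rate=0.6)


class TestTrueDprime:
    def test_reference_sensitivity_at_criterion(self):
        obs = synth.ObserverModel()
        d = synth.true_dprime(obs, (0.0, 0.0), 5.0, 5.0)
        assert d == pytest.approx(2.0729, abs=1e-4)
        # at that d', the response rule is exactly at the 85% criterion
        assert ndtr(d / 2) == pytest.approx(0.85, abs=1e-12)

    def test_zero_tilt_chance(self):
        obs = synth.ObserverModel()
        assert synth.true_dprime(obs, (0.0, 0.0), 0.0, 5.0) == 0.0
        assert synth.response_probability_cw(obs, 0.0, "cw") == 0.5

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            synth.true_dprime(synth.ObserverModel(), (0, 0), 5.0, 0.0)


class TestSimulateResponse:
    def test_closed_form_probabilities(self, rng):
        obs = synth.ObserverModel()
        d = 2.0 * ndtri(0.85)
        n = 10000
        correct = sum(synth.simulate_response(obs, d, "cw", rng) == "cw"
                      for _ in range(n))
        assert binomtest(correct, n, 0.85).pvalue > 1e-4
        # ccw trials: P(report cw) = 1 - 0.85
        cw_reports = sum(synth.simulate_response(obs, d, "ccw", rng) == "cw"
                         for _ in range(n))
        assert binomtest(cw_reports, n, 0.15).pvalue > 1e-4

    def test_full_lapse_is_guessing(self, rng):
        obs = synth.ObserverModel(lapse_rate=0.49)
        p = synth.response_probability_cw(obs, 10.0, "ccw")
        assert p == pytest.approx(0.245 + 0.51 * ndtr(-5.0), abs=1e-9)


class TestGenerateSchedule:
    def test_condition_mix_counts(self):
        scheds = synth.generate_schedule(3000, rng=np.random.default_rng(0))
        counts = pd.Series([s.condition.value for s in scheds]).value_counts()
        for c in counts:
            assert abs(c - 1000) < 4 * math.sqrt(3000 * (1 / 3) * (2 / 3))

    def test_weighting_downweights_far_rows(self):
        scheds = synth.generate_schedule(60000, rng=np.random.default_rng(1))
        rows = []
        for s in scheds:
            if s.condition is Condition.NO_CUE:
                continue
            x, y = s.dt_pos
            if s.saccade_side == "left":
                x = -x
            if s.cue_side == "down":
                y = -y
            rows.append(y)
        y = pd.Series(rows)
        # per-node frequency in the two rows far from the (canonical) cue
        far = (y <= -6).mean() / 9
        near = (y > -6).mean() / 22
        assert far / near == pytest.approx(0.7, abs=0.05)

    def test_weighting_off_uniform(self):
        scheds = synth.generate_schedule(31000, weighting=False,
                                         rng=np.random.default_rng(2))
        xy = pd.Series([s.dt_pos for s in scheds]).value_counts()
        assert xy.max() / xy.min() < 1.5  # no systematic node preference

    def test_dt_onset_window_and_overlap_shift(self, layout):
        from saccmap.geometry import streams_overlap_targets
        for s in synth.generate_schedule(500, rng=np.random.default_rng(3)):
            lay = default_layout(s.saccade_side,
                                 s.cue_side if s.cue_side != "none" else "none")
            if streams_overlap_targets(s.matrix_offset, lay):
                assert 75.0 <= s.dt_onset_ms <= 200.0
            else:
                assert 50.0 <= s.dt_onset_ms <= 175.0
            assert s.fixation_period_ms in np.arange(500.0, 901.0, 50.0)

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError):
            synth.generate_schedule(10, condition_mix=(0.5, 0.5, 0.5))


class TestGazeTraceGeneration:
    def test_noise_free_limit_piecewise_constant(self):
        m = synth.SaccadeModel(fixation_jitter_sd=0.0, landing_sd=0.0,
                               blink_prob=0.0, latency_sd=0.0)
        s = synth.generate_schedule(1, rng=np.random.default_rng(4))[0]
        lay = default_layout(s.saccade_side,
                             s.cue_side if s.cue_side != "none" else "none")
        trace, truth = synth.simulate_gaze_trace(s, m, np.random.default_rng(0), lay)
        pre = trace.t < truth["onset_ms"]
        post = trace.t > truth["onset_ms"] + truth["duration_ms"]
        assert np.ptp(trace.x[pre]) == 0 and np.ptp(trace.y[pre]) == 0
        assert np.allclose(trace.x[post], lay.saccade_target_pos[0])
        # single smooth monotone transition
        seg = trace.x[~pre & ~post]
        d = np.diff(seg)
        assert (d >= 0).all() if lay.saccade_target_pos[0] > 0 else (d <= 0).all()

    def test_main_sequence_duration(self):
        m = synth.SaccadeModel(main_sequence_slope=2.2,
                               main_sequence_intercept=21.0)
        assert m.duration_ms(12.0) == pytest.approx(47.4)

    def test_certain_blink_flags_samples(self, rng):
        m = synth.SaccadeModel(blink_prob=1.0)
        s = synth.generate_schedule(1, rng=np.random.default_rng(5))[0]
        lay = default_layout(s.saccade_side,
                             s.cue_side if s.cue_side != "none" else "none")
        trace, _ = synth.simulate_gaze_trace(s, m, rng, lay)
        assert (~trace.valid).sum() >= 50


class TestSessionLevel:
    def test_determinism_from_seed(self):
        s1 = synth.simulate_session(0, 30, seed=99, keep_traces=True)
        s2 = synth.simulate_session(0, 30, seed=99, keep_traces=True)
        for a, b in zip(s1.trials, s2.trials):
            assert a == b
        for ta, tb in zip(s1.traces, s2.traces):
            assert np.array_equal(ta.x, tb.x, equal_nan=True)

    def test_latency_recovery_within_2se(self, rng):
        """Latencies measured by the detector recover the generator's
        mean/SD split by stream overlap."""
        from saccmap.geometry import streams_overlap_targets
        m = synth.SaccadeModel(blink_prob=0.0)
        lat, overlap = [], []
        lay_cache = {}
        for s in synth.generate_schedule(300, rng=np.random.default_rng(6)):
            key = (s.saccade_side, s.cue_side if s.cue_side != "none" else "none")
            lay = lay_cache.setdefault(key, default_layout(*key))
            trace, truth = synth.simulate_gaze_trace(s, m, rng, lay)
            ev = detect_saccades(smooth_velocity(trace), trace)
            assert len(ev) == 1
            lat.append(ev[0].onset_t - s.fixation_period_ms)
            overlap.append(streams_overlap_targets(s.matrix_offset, lay))
        lat = np.array(lat); overlap = np.array(overlap)
        for ov, mean in ((True, 186.0 + 31.56), (False, 186.0)):
            sub = lat[overlap == ov]
            se = m.latency_sd / math.sqrt(len(sub))
            assert abs(sub.mean() - mean) <= 2 * se + 1.0  # +1 ms onset bias

    def test_attended_nodes_outperform_background(self, poi):
        """Large-n proportion correct at the attention loci exceeds the
        grid-wide mean."""
        session = synth.simulate_session(0, 8000, seed=7, keep_traces=False)
        rows = []
        for t in session.trials:
            if t.condition is not Condition.CUE_SOA200:
                continue
            x, y = t.dt_pos
            if t.saccade_side == "left":
                x = -x
            if t.cue_side == "down":
                y = -y
            rows.append({"node": (x, y),
                         "correct": (t.response == "cw") == (t.dt_tilt > 0)})
        df = pd.DataFrame(rows)
        pc = df.groupby("node")["correct"].mean()
        grand = df["correct"].mean()
        for p in (poi.st, poi.cue, poi.remap):
            assert pc[p] > grand

    def test_inclusion_rate_matches_design_oracle(self, rng):
        """End-to-end inclusion fraction agrees with the timing-level
        Monte-Carlo oracle within 3 percentage points."""
        m = synth.SaccadeModel()
        scheds = synth.generate_schedule(600, rng=np.random.default_rng(8),
                                         participant=0)
        expected = synth.expected_inclusion_rate(scheds, m,
                                                 np.random.default_rng(9),
                                                 n_mc=30000)
        lay_cache = {}
        included = 0
        for s in scheds:
            key = (s.saccade_side, s.cue_side if s.cue_side != "none" else "none")
            lay = lay_cache.setdefault(key, default_layout(*key))
            trace, truth = synth.simulate_gaze_trace(s, m, rng, lay)
            trial = synth.schedule_to_record(s, truth)
            included += process_trial(trial, trace, lay).included
        assert included / len(scheds) == pytest.approx(expected, abs=0.03)
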