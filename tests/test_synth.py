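import math

import numpy as np
import pytest
from scipy import stats as sps

import perisacc as p
from perisacc.synth import (
    CONDITIONS,
    _allocate_conditions,
    _frame_update_time,
    child_rng,
    rate_on_grid,
)


class TestSessionConfig:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            p.SessionConfig(n_trials=10, n_neurons=1,
                            condition_mix=(0.5, 0.2, 0.2, 0.2))

    def test_at_least_one_trial(self):
        with pytest.raises(ValueError):
            p.SessionConfig(n_trials=0, n_neurons=1)

    def test_delay_bounds_ordered(self):
        with pytest.raises(ValueError):
            p.SessionConfig(n_trials=10, n_neurons=1,
                            fixation_to_stim_delay=(700.0, 300.0))


class TestTrialAllocation:
    def test_stratified_counts_exact_at_1200(self):
        cfg = p.SessionConfig(n_trials=1200, n_neurons=1, seed=5)
        slots = _allocate_conditions(cfg)
        counts = {c: sum(1 for cond, _, _ in slots if cond == c) for c in CONDITIONS}
        assert counts == {"control": 600, "sf_change": 200,
                          "shape_change": 200, "combined_change": 200}

    def test_degenerate_mix_all_control(self):
        cfg = p.SessionConfig(n_trials=4, n_neurons=1,
                              condition_mix=(1.0, 0.0, 0.0, 0.0), seed=1)
        bundle = p.generate_session(cfg, include_eye_traces=False)
        assert all(tr.condition == "control" for tr in bundle.trials)
        assert len(bundle.trials) == 4

    def test_proportions_converge_at_10000(self):
        cfg = p.SessionConfig(n_trials=10_000, n_neurons=1, seed=7)
        slots = _allocate_conditions(cfg)
        observed = [sum(1 for cond, _, _ in slots if cond == c) for c in CONDITIONS]
        expected = [q * 10_000 for q in cfg.condition_mix]
        chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
        assert sps.chi2.sf(chi2, df=3) > 0.001

    def test_target_side_balanced(self):
        cfg = p.SessionConfig(n_trials=240, n_neurons=1, seed=2)
        bundle = p.generate_session(cfg, include_eye_traces=False)
        sides = [np.sign(tr.target_x) for tr in bundle.trials]
        assert abs(sum(sides)) <= len(CONDITIONS)  # balanced within each stratum


class TestDeterminism:
    def test_same_seed_identical_bundles(self):
        cfg = p.SessionConfig(n_trials=30, n_neurons=2, seed=9)
        b1 = p.generate_session(cfg)
        b2 = p.generate_session(cfg)
        assert b1 == b2

    def test_different_seed_differs(self):
        b1 = p.generate_session(p.SessionConfig(n_trials=30, n_neurons=1, seed=1))
        b2 = p.generate_session(p.SessionConfig(n_trials=30, n_neurons=1, seed=2))
        assert b1 != b2

    def test_adding_neurons_preserves_trials(self):
        cfg1 = p.SessionConfig(n_trials=20, n_neurons=1, seed=4)
        cfg3 = p.SessionConfig(n_trials=20, n_neurons=3, seed=4)
        b1 = p.generate_session(cfg1)
        b3 = p.generate_session(cfg3)
        assert b1.trials == b3.trials
        assert b1.neurons[0] == b3.neurons[0]


class TestEyeTraceGeneration:
    def test_noise_free_trace_reaches_target(self):
        eye = p.EyeParams(noise_sd=0.0, landing_jitter_sd=0.0,
                          undershoot_frac=0.0, catchup_prob=0.0)
        cfg = p.SessionConfig(n_trials=4, n_neurons=1, seed=3)
        bundle = p.generate_session(cfg, eye=eye)
        for tr in bundle.trials:
            trace = bundle.eye_traces[tr.trial_id]
            d = math.hypot(trace.x[-1] - tr.target_x, trace.y[-1] - tr.target_y)
            assert d < 0.01

    def test_detector_round_trip_on_generated_saccade(self):
        eye = p.EyeParams(noise_sd=0.0, catchup_prob=0.0,
                          landing_jitter_sd=0.0, undershoot_frac=0.0)
        cfg = p.SessionConfig(n_trials=6, n_neurons=1, seed=8)
        bundle = p.generate_session(cfg, eye=eye)
        for tr in bundle.trials:
            events = [e for e in p.detect_saccades(bundle.eye_traces[tr.trial_id])
                      if e.amplitude >= 1.0]
            assert len(events) == 1
            assert 7.0 <= events[0].amplitude <= 9.0

    def test_detected_amplitude_matches_generated_landing(self):
        eye = p.EyeParams(noise_sd=0.0, catchup_prob=0.0)
        cfg = p.SessionConfig(n_trials=6, n_neurons=1, seed=8)
        bundle = p.generate_session(cfg, eye=eye)
        for tr in bundle.trials:
            events = [e for e in p.detect_saccades(bundle.eye_traces[tr.trial_id])
                      if e.amplitude >= 1.0]
            assert len(events) == 1
            true_amp = math.hypot(tr.gt_landing_x, tr.gt_landing_y)
            assert abs(events[0].amplitude - true_amp) < 0.2

    def test_simulated_mode_has_no_saccades(self):
        cfg = p.SessionConfig(n_trials=6, n_neurons=1, seed=8,
                              mode="simulated_saccade")
        bundle = p.generate_session(cfg)
        for tr in bundle.trials:
            events = [e for e in p.detect_saccades(bundle.eye_traces[tr.trial_id])
                      if e.amplitude >= 1.0]
            assert events == []


class TestOnlineUpdate:
    def test_frame_arithmetic(self):
        period = 1000.0 / 85.0
        # exit at 1000 ms lands exactly on frame boundary 85: the update
        # completes at the end of the frame starting there.
        assert _frame_update_time(1000.0, 85.0) == pytest.approx(86 * period)
        # exit mid-frame waits for the next frame start, then one frame
        assert _frame_update_time(1005.0, 85.0) == pytest.approx(87 * period)

    def test_boundary_tie_belongs_to_starting_frame(self):
        period = 1000.0 / 85.0
        assert _frame_update_time(3 * period, 85.0) == pytest.approx(4 * period)

    def test_no_window_exit_returns_none(self):
        t = np.arange(0.0, 500.5, 1.0)
        trace = p.EyeTrace(t=t, x=np.zeros_like(t), y=np.zeros_like(t))
        assert p.simulate_online_update(trace, 0.75, 85.0) is None

    def test_updates_are_intra_saccadic_across_trials(self, real_bundle):
        for tr in real_bundle.trials:
            trace = real_bundle.eye_traces[tr.trial_id]
            ev = [e for e in p.detect_saccades(trace) if e.amplitude >= 1.0][0]
            assert ev.onset <= tr.update_ms <= ev.end

    def test_traceless_generation_matches_frame_grid(self):
        cfg = p.SessionConfig(n_trials=10, n_neurons=1, seed=21)
        bundle = p.generate_session(cfg, include_eye_traces=False)
        period = 1000.0 / 85.0
        for tr in bundle.trials:
            assert tr.update_ms / period == pytest.approx(round(tr.update_ms / period))
            assert tr.gt_saccade_on_ms < tr.update_ms < tr.gt_saccade_end_ms


class TestSpikeGeneration:
    @staticmethod
    def _simple_trial(t_end=2000.0):
        return p.Trial(
            trial_id=0, condition="control", mode="real_saccade",
            pre_sf="low", post_sf="low", pre_shape="circle", post_shape="circle",
            target_x=8.0, target_y=0.0, fix_on_ms=0.0, stim_on_ms=400.0,
            go_ms=1000.0, update_ms=1200.0, trial_end_ms=t_end,
            gt_saccade_on_ms=1180.0, gt_saccade_end_ms=1226.0,
        )

    def test_pure_baseline_count_is_poisson(self):
        trial = self._simple_trial()
        gt = p.GroundTruthNeuron(
            baseline_rate=20.0, release_transient_amp=0.0, pause_depth=0.0,
            burst_amp_low_sf=0.0, burst_amp_high_sf=0.0, onset_response_amp=0.0)
        counts = [len(p.generate_spike_train(trial, gt, child_rng(17, i)))
                  for i in range(1000)]
        expected = 20.0 * trial.trial_end_ms / 1000.0  # 40 spikes
        se = math.sqrt(expected / 1000)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_zero_rate_gives_empty_train(self):
        trial = self._simple_trial()
        gt = p.GroundTruthNeuron(
            baseline_rate=0.0, release_transient_amp=0.0,
            burst_amp_low_sf=0.0, burst_amp_high_sf=0.0, onset_response_amp=0.0)
        assert len(p.generate_spike_train(trial, gt, child_rng(1, 0))) == 0

    def test_count_conservation_full_model(self):
        """Mean spike count matches the rate integral (closed-form oracle)."""
        trial = self._simple_trial()
        gt = p.default_neuron()
        # independent closed form: baseline minus pause and suppression
        # losses, plus truncated-Gaussian bump masses
        T = trial.trial_end_ms

        def bump_mass(amp, center, sigma):
            lo = sps.norm.cdf((0 - center) / sigma)
            hi = sps.norm.cdf((T - center) / sigma)
            return amp * sigma * math.sqrt(2 * math.pi) / 1000.0 * (hi - lo)

        base = gt.baseline_rate * T / 1000.0
        pause_loss = gt.pause_depth * gt.baseline_rate * (
            trial.gt_saccade_end_ms + 10.0 - trial.gt_saccade_on_ms) / 1000.0
        supp_depth = min(1.0, -gt.onset_response_amp / gt.baseline_rate)
        supp_loss = supp_depth * gt.baseline_rate * (160.0 - 40.0) / 1000.0
        release = bump_mass(gt.release_transient_amp, trial.go_ms + 80.0, 30.0)
        # release bump overlaps the pause window: remove its thinned share
        zs = (trial.gt_saccade_on_ms - (trial.go_ms + 80.0)) / 30.0
        ze = (trial.gt_saccade_end_ms + 10.0 - (trial.go_ms + 80.0)) / 30.0
        release_in_pause = gt.release_transient_amp * 30.0 * math.sqrt(2 * math.pi) \
            / 1000.0 * (sps.norm.cdf(ze) - sps.norm.cdf(zs))
        release -= gt.pause_depth * release_in_pause
        burst = bump_mass(gt.burst_amp_low_sf, trial.update_ms + 60.0, 15.0)
        expected = base - pause_loss - supp_loss + release + burst

        counts = [len(p.generate_spike_train(trial, gt, child_rng(23, i)))
                  for i in range(1500)]
        se = np.std(counts) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se
        # the diagnostic rate function integrates to the same expectation
        grid = np.arange(0, T, 0.25)
        numeric = np.trapezoid(rate_on_grid(trial, gt, grid), grid) / 1000.0
        assert numeric == pytest.approx(expected, rel=0.01)

    def test_change_trials_have_higher_peak_rate(self):
        gt = p.default_neuron(gain_sf_change=1.5)
        cfg = p.SessionConfig(n_trials=400, n_neurons=1, seed=31,
                              condition_mix=(0.5, 0.5, 0.0, 0.0))
        bundle = p.generate_session(cfg, neurons=[gt], include_eye_traces=False)
        rec = bundle.neurons[0]
        means = {}
        for sf in ("low", "high"):
            trials = [t for t in bundle.trials if t.post_sf == sf]
            rasters = p.align_spikes(rec.spikes, trials)
            w = p.measurement_window(sf)
            means[sf] = {c: p.peak_response(r, w).value
                         for c, r in rasters.items()}
        for sf in ("low", "high"):
            assert means[sf]["sf_change"] > means[sf]["control"]

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            p.GroundTruthNeuron(burst_amp_low_sf=-1.0)

    def test_latency_ordering_enforced(self):
        with pytest.raises(ValueError):
            p.GroundTruthNeuron(burst_latency_low_sf=90.0,
                                burst_latency_high_sf=60.0)


class TestBundleInvariants:
    def test_event_ordering(self, real_bundle, sim_bundle):
        for bundle in (real_bundle, sim_bundle):
            bundle.validate()  # raises on violation
        for tr in real_bundle.trials:
            assert tr.fix_on_ms < tr.stim_on_ms < tr.go_ms < tr.update_ms \
                < tr.trial_end_ms

    def test_every_trial_has_one_update(self, sim_bundle):
        assert all(tr.update_ms is not None for tr in sim_bundle.trials)
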