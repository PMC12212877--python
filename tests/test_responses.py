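import math

import numpy as np
import pytest

import perisacc as p
from perisacc.responses import (
    DEFAULT_KERNEL_SD,
    MIN_CONTROL_RATE,
    _per_trial_curves,
)
from perisacc.synth import child_rng


def make_trial(trial_id=0, condition="control", post_sf="low",
               update=1500.0, stim_on=400.0, mode="real_saccade"):
    return p.Trial(
        trial_id=trial_id, condition=condition, mode=mode,
        pre_sf=post_sf, post_sf=post_sf, pre_shape="circle",
        post_shape="circle", target_x=8.0, target_y=0.0,
        fix_on_ms=0.0, stim_on_ms=stim_on,
        go_ms=1000.0 if mode == "real_saccade" else None,
        update_ms=update, trial_end_ms=update + 700.0,
        gt_saccade_on_ms=1450.0, gt_saccade_end_ms=1495.0,
    )


class TestAlignSpikes:
    def test_relative_time_is_subtraction(self):
        trial = make_trial(update=1500.0)
        rasters = p.align_spikes({0: np.array([1510.0])}, [trial])
        assert rasters["control"].trials[0] == pytest.approx([10.0])

    def test_empty_trial_retained(self):
        trials = [make_trial(0), make_trial(1)]
        rasters = p.align_spikes({0: np.array([1510.0])}, trials)
        assert rasters["control"].n_trials == 2
        assert rasters["control"].trials[1].size == 0

    def test_missing_event_raises_with_trial(self):
        trial = make_trial(mode="simulated_saccade")
        with pytest.raises(ValueError, match="trial 0"):
            p.align_spikes({0: np.array([1510.0])}, [trial], event="go")

    def test_excluded_trials_dropped(self):
        trials = [make_trial(0), make_trial(1)]
        rasters = p.align_spikes({}, trials, include={1: False})
        assert rasters["control"].trial_ids == [0]

    def test_span_crops_spikes(self):
        trial = make_trial(update=1500.0)
        rasters = p.align_spikes({0: np.array([1000.0, 1510.0, 1900.0])},
                                 [trial], span=(-300.0, 300.0))
        assert rasters["control"].trials[0] == pytest.approx([10.0])


class TestRateCurve:
    def test_homogeneous_poisson_recovers_rate(self):
        rng = child_rng(41)
        rate, n_trials = 50.0, 500
        span = (-300.0, 300.0)
        trials = []
        for _ in range(n_trials):
            n = rng.poisson(rate * 0.6)
            trials.append(np.sort(rng.uniform(*span, n)))
        raster = p.AlignedRaster(neuron_id=0, condition="control",
                                 alignment="update", trials=trials,
                                 trial_ids=list(range(n_trials)), span=span)
        curve = p.estimate_rate_curve(raster)
        interior = (curve.t > span[0] + 50) & (curve.t < span[1] - 50)
        z = (curve.rate[interior] - rate) / np.where(
            curve.sem[interior] > 0, curve.sem[interior], 1.0)
        assert np.all(np.abs(z) < 4.0)
        assert abs(curve.rate[interior].mean() - rate) < 3 * curve.sem[interior].mean()

    def test_single_spike_kernel_mass_is_one(self):
        raster = p.AlignedRaster(neuron_id=0, condition="control",
                                 alignment="update",
                                 trials=[np.array([0.0])], trial_ids=[0],
                                 span=(-300.0, 300.0))
        curve = p.estimate_rate_curve(raster, grid_step=0.5)
        integral = np.trapezoid(curve.rate, curve.t) / 1000.0
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_no_spikes_gives_zero_curve(self):
        raster = p.AlignedRaster(neuron_id=0, condition="control",
                                 alignment="update",
                                 trials=[np.empty(0), np.empty(0)],
                                 trial_ids=[0, 1], span=(-300.0, 300.0))
        curve = p.estimate_rate_curve(raster)
        assert np.all(curve.rate == 0.0)

    def test_bad_grid_step_rejected(self):
        raster = p.AlignedRaster(neuron_id=0, condition="control",
                                 alignment="update", trials=[np.empty(0)],
                                 trial_ids=[0], span=(-300.0, 300.0))
        with pytest.raises(ValueError):
            p.estimate_rate_curve(raster, grid_step=0.0)


class TestPeakResponse:
    @staticmethod
    def _raster(trials, span=(-300.0, 300.0)):
        return p.AlignedRaster(neuron_id=0, condition="x", alignment="update",
                               trials=trials, trial_ids=list(range(len(trials))),
                               span=span)

    def test_peak_matches_direct_kernel_evaluation(self):
        spikes = np.array([48.0, 50.0, 51.0, 53.0, 55.0])
        raster = self._raster([spikes])
        m = p.peak_response(raster, (0.0, 120.0))
        grid = np.arange(0.0, 120.5, 1.0)
        norm = 1000.0 / (DEFAULT_KERNEL_SD * math.sqrt(2 * math.pi))
        direct = (norm * np.exp(-0.5 * ((grid[:, None] - spikes[None, :])
                                        / DEFAULT_KERNEL_SD) ** 2)).sum(axis=1)
        assert m.per_trial_peaks[0] == pytest.approx(direct.max())
        assert m.value == pytest.approx(direct.max())

    def test_spike_free_trial_has_zero_peak(self):
        raster = self._raster([np.empty(0), np.array([60.0])])
        m = p.peak_response(raster, (0.0, 120.0))
        assert m.per_trial_peaks[0] == 0.0
        assert m.per_trial_peaks[1] > 0.0

    def test_window_width_controls_burst_visibility(self):
        burst_at_130 = np.array([128.0, 130.0, 131.0, 133.0])
        raster = self._raster([burst_at_130])
        narrow = p.peak_response(raster, (0.0, 120.0))
        wide = p.peak_response(raster, (0.0, 150.0))
        assert wide.value > 5 * max(narrow.value, 1.0)

    def test_window_discipline_bitwise(self):
        """Perturbing spikes outside the window leaves the measure unchanged."""
        inside = np.array([30.0, 65.0, 80.0])
        raster_a = self._raster([np.concatenate([inside, [-50.0, 180.0]])])
        raster_b = self._raster([np.concatenate([inside, [-250.0, 299.0]])])
        m_a = p.peak_response(raster_a, (0.0, 120.0))
        m_b = p.peak_response(raster_b, (0.0, 120.0))
        assert m_a.per_trial_peaks[0] == m_b.per_trial_peaks[0]
        assert m_a.value == m_b.value

    def test_window_outside_span_rejected(self):
        raster = self._raster([np.array([10.0])], span=(-100.0, 100.0))
        with pytest.raises(ValueError):
            p.peak_response(raster, (0.0, 150.0))

    def test_peak_of_mean_switch(self):
        raster = self._raster([np.array([60.0]), np.array([90.0])])
        per_trial = p.peak_response(raster, (0.0, 120.0))
        of_mean = p.peak_response(raster, (0.0, 120.0), peak_of_mean=True)
        # two offset spikes: mean curve peak < mean of single-spike peaks
        assert of_mean.value < per_trial.value


class TestScreening:
    @staticmethod
    def _spikes_for(trials, gt, seed):
        return {tr.trial_id: p.generate_spike_train(tr, gt, child_rng(seed, tr.trial_id))
                for tr in trials}

    @staticmethod
    def _trials(n=60):
        return [make_trial(i) for i in range(n)]

    def test_onset_burst_neuron_excluded(self):
        gt = p.default_neuron(onset_response_amp=30.0)
        trials = self._trials()
        res = p.screen_neuron(self._spikes_for(trials, gt, 51), trials)
        assert res.extrafoveal_onset_elevated
        assert not res.included

    def test_onset_suppressed_neuron_included(self):
        gt = p.default_neuron(onset_response_amp=-8.0)  # post < pre
        trials = self._trials()
        res = p.screen_neuron(self._spikes_for(trials, gt, 52), trials)
        assert not res.extrafoveal_onset_elevated
        assert res.control_window_rate >= MIN_CONTROL_RATE
        assert res.included

    def test_low_control_rate_excluded(self):
        gt = p.burst_dominated_neuron(baseline_rate=1.0, burst_amp_low_sf=3.0,
                                      burst_amp_high_sf=3.0)
        trials = self._trials()
        res = p.screen_neuron(self._spikes_for(trials, gt, 53), trials)
        assert res.control_window_rate < MIN_CONTROL_RATE
        assert not res.included

    def test_no_control_trials_is_error(self):
        trials = [make_trial(0, condition="sf_change")]
        with pytest.raises(ValueError, match="control"):
            p.screen_neuron({}, trials)

    def test_population_screening_exact(self):
        """Exactly the constructed offenders are excluded from a population."""
        specs = [p.default_neuron(),  # clean -> included
                 p.default_neuron(onset_response_amp=20.0),  # onset burst
                 p.burst_dominated_neuron(baseline_rate=0.5, burst_amp_low_sf=2.0,
                                          burst_amp_high_sf=2.0),  # weak
                 p.default_neuron(onset_response_amp=-6.0)]  # suppressed, ok
        cfg = p.SessionConfig(n_trials=80, n_neurons=4, seed=54)
        bundle = p.generate_session(cfg, neurons=specs, include_eye_traces=False)
        included = [p.screen_neuron(rec.spikes, bundle.trials).included
                    for rec in bundle.neurons]
        assert included == [True, False, False, True]


class TestNormalizePopulation:
    @staticmethod
    def _curves_from(seed, gain=1.5, n_trials=300):
        gt = p.default_neuron(gain_sf_change=gain)
        cfg = p.SessionConfig(n_trials=n_trials, n_neurons=1, seed=seed,
                              condition_mix=(0.5, 0.5, 0.0, 0.0))
        bundle = p.generate_session(cfg, neurons=[gt], include_eye_traces=False)
        rec = bundle.neurons[0]
        trials = [t for t in bundle.trials if t.post_sf == "low"]
        rasters = p.align_spikes(rec.spikes, trials)
        return (p.estimate_rate_curve(rasters["sf_change"]),
                p.estimate_rate_curve(rasters["control"]))

    def test_control_self_normalizes_to_one(self):
        cond, ctrl = self._curves_from(61)
        pop = p.normalize_population([(ctrl, ctrl)])
        assert pop.rate.max() == pytest.approx(1.0)

    def test_identical_neurons_have_zero_sem(self):
        cond, ctrl = self._curves_from(62)
        pop = p.normalize_population([(cond, ctrl)] * 3)
        assert np.allclose(pop.sem, 0.0)
        single = p.normalize_population([(cond, ctrl)])
        assert np.allclose(pop.rate, single.rate)

    def test_gain_elevates_normalized_change_peak(self):
        pairs = [self._curves_from(63 + k) for k in range(5)]
        pop_change = p.normalize_population(pairs)
        pop_control = p.normalize_population([(c, c) for _, c in pairs])
        assert pop_change.rate.max() > pop_control.rate.max()

    def test_degenerate_control_skipped_with_warning(self):
        cond, ctrl = self._curves_from(68)
        dead = p.RateCurve(t=ctrl.t, rate=np.zeros_like(ctrl.rate),
                           sem=np.zeros_like(ctrl.rate), n=ctrl.n)
        with pytest.warns(RuntimeWarning, match="control peak"):
            pop = p.normalize_population([(cond, ctrl), (cond, dead)])
        assert pop.n == 1


class TestAlignmentRobustness:
    def test_saccade_end_alignment_preserves_effect_sign(self):
        """The population effect direction survives re-alignment to saccade end."""
        gt = p.default_neuron(gain_sf_change=1.5)
        cfg = p.SessionConfig(n_trials=400, n_neurons=1, seed=71,
                              condition_mix=(0.5, 0.5, 0.0, 0.0))
        bundle = p.generate_session(cfg, neurons=[gt] * 1, include_eye_traces=False)
        rec = bundle.neurons[0]
        for event in ("update", "gt_saccade_end"):
            diffs = []
            for sf in ("low", "high"):
                trials = [t for t in bundle.trials if t.post_sf == sf]
                rasters = p.align_spikes(rec.spikes, trials, event=event)
                w = p.measurement_window(sf)
                diffs.append(p.peak_response(rasters["sf_change"], w).value
                             - p.peak_response(rasters["control"], w).value)
            assert all(d > 0 for d in diffs), event
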