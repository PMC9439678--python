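"""SDFs, onset detection, quartile and integration analyses."""

import numpy as np
import pandas as pd
import pytest

from neuropose import synth, timecourse as tc
from neuropose.datasets import NeuronDataset
from neuropose.design import TaskDesign
from conftest import make_tilt_dataset


class TestSDF:
    def test_kernel_unit_area_and_positive_taus(self):
        k = tc.double_exponential_kernel(1.0, 20.0)
        assert k.sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            tc.double_exponential_kernel(0.0, 20.0)

    def test_empty_train_gives_zero_sdf(self):
        s = tc.sdf(np.empty(0), 0.0, 500.0)
        assert np.all(s.rate == 0.0)

    def test_single_spike_mass_conserved(self):
        s = tc.sdf(np.array([100.0]), 0.0, 800.0)
        assert s.rate.sum() / 1000.0 == pytest.approx(1.0, abs=1e-6)

    def test_homogeneous_rate_recovered(self):
        """Mean SDF over many Poisson trials ~ the true rate after the
        kernel settles."""
        rng = np.random.default_rng(0)
        trains = []
        for _ in range(10_000):
            n = rng.poisson(50.0 * 0.4)
            trains.append(np.sort(rng.uniform(0, 400.0, n)))
        _, mat = tc.sdf_matrix(trains, 0.0, 400.0)
        settled = mat[:, 150:].mean()
        assert settled == pytest.approx(50.0, rel=0.02)


class TestSustainedRun:
    def test_run_detection(self):
        sig = np.zeros(100, dtype=bool)
        sig[40:75] = True
        assert tc.sustained_run(sig, 30) == 40
        sig[40:75] = False
        sig[40:60] = True  # only 20 ms
        assert tc.sustained_run(sig, 30) is None


def step_dataset(rate0, rate1, step_ms, n_trials, seed, duration=600.0,
                 fixation=300.0):
    """Dataset whose rate steps from rate0 to rate1 at step_ms."""
    rng = np.random.default_rng(seed)
    grid = np.arange(-fixation, duration)
    prof = np.where(grid >= step_ms, rate1, rate0).astype(float)
    times = synth._spikes_from_profile(np.tile(prof, (n_trials, 1)),
                                       -fixation, rng)
    design = TaskDesign(stimulus_duration=duration, fixation_duration=fixation)
    rows = [(45.0, 30.0, 57.0,
             np.count_nonzero((t >= 46.0) & (t < duration)), np.nan)
            for t in times]
    return make_tilt_dataset(rows, design, spike_times=times,
                             response_window=(46.0, duration))


class TestVisualLatency:
    def test_step_response_detected_near_true_onset(self):
        data = step_dataset(10.0, 40.0, 50.0, 500, seed=1)
        lat = tc.visual_latency(data)
        assert lat is not None
        assert 50.0 <= lat <= 62.0  # kernel delay allowed

    def test_unmodulated_neuron_returns_none(self):
        data = step_dataset(15.0, 15.0, 50.0, 200, seed=2)
        assert tc.visual_latency(data) is None

    def test_brief_transient_fails_sustain_rule(self):
        """A modulation shorter than 30 ms is rejected.  A narrow
        kernel keeps the SDF transient shorter than the sustain
        requirement (the default 20 ms decay would smear it past it)."""
        rng = np.random.default_rng(3)
        grid = np.arange(-300.0, 600.0)
        prof = np.full(grid.size, 10.0)
        prof[(grid >= 50) & (grid < 70)] = 120.0  # 20 ms transient
        times = synth._spikes_from_profile(np.tile(prof, (300, 1)), -300.0, rng)
        design = TaskDesign(stimulus_duration=600.0)
        rows = [(45.0, 30.0, 57.0, 1, np.nan) for _ in times]
        data = make_tilt_dataset(rows, design, spike_times=times,
                                 response_window=(46.0, 600.0))
        assert tc.visual_latency(data, tau_decay=2.0) is None
        # the same kernel still detects a sustained step
        step = step_dataset(10.0, 40.0, 50.0, 500, seed=1)
        assert tc.visual_latency(step, tau_decay=2.0) is not None


class TestDivergenceOnset:
    def test_identical_groups_give_none(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, (10, 300)) for _ in range(8)]
        assert tc.divergence_onset(groups, np.arange(300.0)) is None

    def test_injected_divergence_recovered(self):
        rng = np.random.default_rng(5)
        t = np.arange(400.0)
        groups = []
        for g in range(8):
            base = rng.normal(0, 0.2, (12, 400))
            base[:, 200:] += g  # clean separation from 200 ms
            groups.append(base)
        onset = tc.divergence_onset(groups, t)
        assert onset == pytest.approx(200.0, abs=5.0)

    def test_brief_divergence_rejected(self):
        rng = np.random.default_rng(6)
        groups = []
        for g in range(8):
            base = rng.normal(0, 0.2, (12, 400))
            base[:, 200:210] += g  # 10 ms only
            groups.append(base)
        assert tc.divergence_onset(groups, np.arange(400.0)) is None


class TestSaccadeOnsetFromEye:
    def test_threshold_crossing(self):
        v = np.zeros(400)
        v[180:] = 200.0
        assert tc.saccade_onset_from_eye(v) == 180.0

    def test_never_crossing_raises(self):
        with pytest.raises(ValueError):
            tc.saccade_onset_from_eye(np.full(300, 100.0))


class TestLatencyQuartiles:
    def test_rank_partition_and_means(self):
        lat = np.arange(1.0, 9.0)
        curves = np.tile(np.linspace(0, 1, 50), (8, 1))
        qa = tc.latency_quartile_analysis(lat, curves, np.arange(-40.0, 10.0),
                                          baseline_window=(-40.0, -30.0))
        assert np.allclose(qa.quartile_mean_latencies, [1.5, 3.5, 5.5, 7.5])

    def test_identical_curves_coalesce_at_earliest_sample(self):
        one = np.full(500, 10.0)
        curves = np.tile(one, (16, 1))
        t = np.arange(-400.0, 100.0)
        qa = tc.latency_quartile_analysis(np.repeat([1.0, 2.0, 3.0, 4.0], 4),
                                          curves, t,
                                          baseline_window=(-400.0, -350.0))
        # identical curves: zero deviation everywhere, no detected
        # starts -> earliest candidate time wins the tie-break
        assert qa.coalescence_time == -400.0
        assert all(s is None for s in qa.starts)

    def test_degenerate_latencies_flagged(self):
        curves = np.random.default_rng(8).normal(0, 1, (12, 100))
        qa = tc.latency_quartile_analysis(np.full(12, 150.0), curves,
                                          np.arange(-90.0, 10.0),
                                          baseline_window=(-90.0, -60.0))
        assert qa.degenerate
        assert np.allclose(qa.quartile_mean_latencies, 150.0)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            tc.latency_quartile_analysis(np.arange(5.0), np.zeros((5, 10)),
                                         np.arange(10.0))


class TestIntegrateAndMatch:
    def test_constant_source_integrates_to_ramp(self):
        t = np.arange(-100.0, 100.0)
        src = np.full(t.size, 5.0)
        src[t < 0] = 0.0
        out = tc.integrate_and_match(src, 0.0, np.zeros(t.size), 99.0, t)[0]
        # cumulative sum of a constant c is a ramp of slope c
        w = t >= 0
        ramp = np.cumsum(np.where(w, 5.0, 0.0))[w]
        fitted = (out["matched"][w] - out["offset"]) / out["gain"] \
            if out["gain"] != 0 else None
        assert np.allclose(np.diff(ramp), 5.0)

    def test_exact_affine_recovery(self):
        rng = np.random.default_rng(9)
        t = np.arange(-50.0, 200.0)
        src = np.where(t >= 0, rng.uniform(1, 3, t.size), 0.0)
        integ = np.cumsum(np.where(t >= 0, src, 0.0))
        target = 4.0 + 2.5 * integ
        out = tc.integrate_and_match(src, 0.0, target, 199.0, t)[0]
        assert out["offset"] == pytest.approx(4.0, abs=1e-8)
        assert out["gain"] == pytest.approx(2.5, abs=1e-10)
        assert out["sse"] < 1e-10

    def test_empty_window_rejected(self):
        t = np.arange(100.0)
        with pytest.raises(ValueError):
            tc.integrate_and_match(np.ones(100), 150.0, np.ones(100), 120.0, t)


class TestPopulationChoiceTimecourses:
    def test_preferred_curve_has_maximal_window_mean(self, design):
        rng = np.random.default_rng(10)
        neurons = []
        for i in range(8):
            cm = {"onset_ms": 190.0, "depth": 25.0,
                  "preferred_choice": float(rng.choice(design.choice_directions)),
                  "kappa": 4.7}
            truth = synth.make_ground_truth(design, rng, choice_modulation=cm)
            neurons.append(synth.simulate_neuron(
                truth, design, 8, seed=800 + i, spike_times="frontoparallel"))
        res = tc.population_choice_timecourses(neurons)
        assert res.n_neurons >= 4
        w = res.time >= (res.onset if res.onset is not None else 190.0)
        means = res.curves[:, w].mean(axis=1)
        assert np.argmax(means) == 0  # relative choice 0 = preferred

    def test_no_neurons_tuned_returns_empty(self, design):
        rng = np.random.default_rng(11)
        neurons = [synth.simulate_neuron(
            synth.make_ground_truth(design, rng), design, 3,
            seed=900 + i, spike_times="frontoparallel") for i in range(3)]
        res = tc.population_choice_timecourses(neurons, alpha=1e-12)
        assert res.onset is None
        assert res.n_neurons == 0
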