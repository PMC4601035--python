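"""Preprocessing chain and P3 extraction, anchored to closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from oracles import template_window_mean

from p3net.erp import (average_erp, bandpass, baseline_correct, epoch,
                       extract_p3, reject_artifacts, rereference_average)
from p3net.io import DEFAULT_CHANNELS, Recording
from p3net.simulate import (P3_SPATIAL_WEIGHTS, CohortSpec, SubjectTruth,
                            p3_template, simulate_cohort, simulate_task)


def _rec(data, fs=500.0):
    labels = [f"ch{i}" for i in range(data.shape[0])]
    return Recording(data=data, fs=fs, labels=labels)


class TestRereference:
    def test_common_signal_vanishes(self):
        wave = np.sin(np.arange(100) / 7.0) + 3.0
        data = np.tile(wave, (3, 1))
        out = rereference_average(_rec(data))
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_column_sums_zero_and_idempotent(self, rng):
        rec = _rec(rng.normal(0, 10, size=(5, 400)))
        once = rereference_average(rec)
        assert np.max(np.abs(once.data.sum(axis=0))) < 1e-9
        twice = rereference_average(once)
        assert np.allclose(twice.data, once.data, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            rereference_average(_rec(np.zeros((1, 10))))


class TestBandpass:
    fs = 500.0

    def _tone(self, hz, secs=20.0):
        t = np.arange(int(secs * self.fs)) / self.fs
        return np.sin(2 * np.pi * hz * t)

    def test_passband_tone_preserved(self):
        x = self._tone(3.0)
        out = bandpass(_rec(x[None, :].repeat(2, 0)), 0.5, 6.0)
        core = slice(2000, -2000)  # avoid edge transients
        ratio = out.data[0, core].std() / x[core].std()
        assert abs(ratio - 1.0) < 0.05

    def test_stopband_tone_attenuated_20db(self):
        x = self._tone(25.0)
        out = bandpass(_rec(x[None, :].repeat(2, 0)), 0.5, 6.0)
        core = slice(2000, -2000)
        ratio = out.data[0, core].std() / x[core].std()
        assert 20 * np.log10(1.0 / ratio) >= 20.0

    def test_zero_phase(self):
        x = self._tone(3.0)
        out = bandpass(_rec(x[None, :].repeat(2, 0)), 0.5, 6.0)
        xc = np.correlate(out.data[0, 2000:-2000], x[2000:-2000], "full")
        lag = int(np.argmax(xc)) - (len(xc) // 2)
        assert lag == 0

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            bandpass(_rec(np.zeros((2, 100))), 6.0, 0.5)


class TestEpoching:
    def test_constant_channel_zero_after_baseline(self):
        data = np.full((2, 2000), 7.5)
        ev = pd.DataFrame({"onset_sample": [500, 1200],
                           "label": ["target", "standard"]})
        eps = baseline_correct(epoch(_rec(data), ev))
        assert np.allclose(eps.epochs, 0.0, atol=1e-12)

    def test_baseline_window_mean_is_zero(self, rng):
        data = rng.normal(0, 10, size=(3, 4000))
        ev = pd.DataFrame({"onset_sample": [600, 1500, 2500],
                           "label": ["target"] * 3})
        eps = baseline_correct(epoch(_rec(data), ev))
        times = eps.times_ms()
        base = (times >= -200) & (times < 0)
        assert np.max(np.abs(eps.epochs[:, :, base].mean(axis=-1))) < 1e-9

    def test_event_near_edge_dropped(self):
        data = np.zeros((2, 1000))
        ev = pd.DataFrame({"onset_sample": [10, 500],
                           "label": ["target", "target"]})
        with pytest.warns(UserWarning, match="edge"):
            eps = epoch(_rec(data), ev)
        assert list(eps.kept) == [False, True]


class TestRejection:
    def _eps(self, peak_uv):
        data = np.zeros((2, 3000))
        data[0, 1000] = peak_uv
        ev = pd.DataFrame({"onset_sample": [950, 2000],
                           "label": ["target", "target"]})
        return epoch(_rec(data), ev)

    def test_above_threshold_rejected(self):
        eps = reject_artifacts(self._eps(80.0))
        assert list(eps.kept) == [False, True]

    def test_within_threshold_kept(self):
        eps = reject_artifacts(self._eps(74.0))
        assert list(eps.kept) == [True, True]


class TestAveraging:
    def test_identical_and_cancelling_trials(self):
        data = np.zeros((1, 4000))
        v = np.sin(np.arange(500) / 20.0)
        for onset, sign in [(500, 1), (1500, 1), (2500, -1)]:
            data[0, onset - 100:onset + 400] = sign * v
        ev = pd.DataFrame({"onset_sample": [500, 1500, 2500],
                           "label": ["a", "a", "b"]})
        eps = epoch(_rec(data), ev)
        avg = average_erp(eps, "a")
        assert np.allclose(avg[0], eps.epochs[0, 0], atol=1e-12)
        with pytest.raises(ValueError, match="no kept trials"):
            average_erp(eps, "c")
        both = epoch(_rec(data), pd.DataFrame(
            {"onset_sample": [500, 2500], "label": ["m", "m"]}))
        assert np.allclose(average_erp(both, "m"), 0.0, atol=1e-12)


class TestExtractP3:
    def _erp_with_template(self, amp, lat, width=150.0, fs=500.0):
        """Noise-free ERP: template on all five P3 channels, weight 1."""
        n = int(1.0 * fs)  # -200..800 ms
        erp = np.zeros((len(DEFAULT_CHANNELS), n))
        tmpl = p3_template(amp, lat, width, fs)
        start = int(0.2 * fs)
        for ch in ("CPz", "CP1", "CP2", "Cz", "Pz"):
            row = list(DEFAULT_CHANNELS).index(ch)
            erp[row, start:start + len(tmpl)] = tmpl[:n - start]
        return erp

    def test_closed_form_amplitude_and_exact_latency(self):
        amp, lat, width = 5.0, 400.0, 150.0
        erp = self._erp_with_template(amp, lat, width)
        m = extract_p3(erp, DEFAULT_CHANNELS, 500.0)
        oracle = template_window_mean(amp, width)
        assert m.latency == lat
        assert m.amplitude == pytest.approx(oracle, abs=1e-9)
        assert m.per_channel["CPz"][0] == pytest.approx(oracle, abs=1e-9)

    def test_tie_breaks_to_earliest_peak(self):
        erp = np.zeros((len(DEFAULT_CHANNELS), 500))
        idx350 = int((350 + 200) / 2)
        idx450 = int((450 + 200) / 2)
        erp[:, idx350] = erp[:, idx450] = 3.0
        m = extract_p3(erp, DEFAULT_CHANNELS, 500.0)
        assert m.latency == 350.0

    def test_all_zero_erp_degenerate(self):
        erp = np.zeros((len(DEFAULT_CHANNELS), 500))
        m = extract_p3(erp, DEFAULT_CHANNELS, 500.0)
        assert m.amplitude == 0.0
        assert m.latency == 300.0

    def test_missing_channel_and_short_window_errors(self):
        erp = np.zeros((3, 500))
        with pytest.raises(KeyError):
            extract_p3(erp, ["a", "b", "c"], 500.0)
        erp = np.zeros((len(DEFAULT_CHANNELS), 100))
        with pytest.raises(ValueError, match="cannot cover"):
            extract_p3(erp, DEFAULT_CHANNELS, 500.0, window_ms=(-200.0, 0.0))

    def test_constant_shift_moves_amplitude_only(self):
        erp = self._erp_with_template(4.0, 380.0)
        m0 = extract_p3(erp, DEFAULT_CHANNELS, 500.0)
        m1 = extract_p3(erp + 2.5, DEFAULT_CHANNELS, 500.0)
        assert m1.latency == m0.latency
        assert m1.amplitude == pytest.approx(m0.amplitude + 2.5, abs=1e-9)


def test_noiseless_cohort_recovery_is_exact():
    """Epoch/baseline/average on a noise-free cohort reproduces the
    planted template to numerical precision (no filtering, no re-reference)."""
    spec = CohortSpec(n_subjects=3, rest_duration=20.0, n_trials=20,
                      noise_sd=0.0, artifact_rate=0.0, seed=5)
    subjects, truths = simulate_cohort(spec)
    for sub, truth in zip(subjects, truths):
        eps = baseline_correct(epoch(sub["task"], sub["events"]))
        erp = average_erp(eps, "target")
        m = extract_p3(erp, eps.labels, eps.fs)
        oracle = template_window_mean(truth.true_amp, spec.p3_width_ms)
        assert m.latency == truth.true_lat
        assert m.per_channel["CPz"][0] == pytest.approx(oracle, abs=1e-9)
        w5 = np.mean([P3_SPATIAL_WEIGHTS[c]
                      for c in ("CPz", "CP1", "CP2", "Cz", "Pz")])
        assert m.amplitude == pytest.approx(w5 * oracle, abs=1e-9)


def test_latency_error_small_under_moderate_noise():
    """Mean absolute latency error stays below 20 ms with 2 uV noise."""
    errors = []
    for seed in range(10):
        spec = CohortSpec(n_subjects=3, rest_duration=20.0, n_trials=150,
                          noise_sd=2.0, artifact_rate=0.0, seed=100 + seed)
        subjects, truths = simulate_cohort(spec)
        sub, truth = subjects[0], truths[0]
        rec = bandpass(rereference_average(sub["task"]), 0.5, 6.0)
        eps = baseline_correct(epoch(rec, sub["events"]))
        erp = average_erp(eps, "target")
        m = extract_p3(erp, eps.labels, eps.fs)
        errors.append(abs(m.latency - truth.true_lat))
    assert np.mean(errors) < 20.0
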