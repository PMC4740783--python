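"""Synthetic population, rate model, Poisson spiking and voltage synthesis."""

import numpy as np
import pytest
from scipy import stats

from vocdisc import (
    StimulusSet,
    UnitSpec,
    generate_population,
    load_recordings,
    save_recordings,
    simulate_responses,
    synthesize_voltage,
)
from vocdisc.stimuli import StimulusTemplate, generate_vocalization_set
from vocdisc.synthetic import default_spike_template, stimulus_drive


class TestPopulation:
    def test_linear_shank_bfs_increase_along_contacts(self):
        pop = generate_population("linear_double_shank", 16, (0.5, 23.0), seed=3)
        bfs = [u.bf for u in pop.units]
        assert bfs == sorted(bfs)
        assert bfs[0] == pytest.approx(0.5)
        assert bfs[-1] == pytest.approx(23.0)
        assert pop.units[3].position == (0, 3, 300.0)

    def test_tetrode_bfs_within_range(self):
        pop = generate_population("tetrode", 8, (6.3, 8.0), seed=3)
        for u in pop.units:
            assert 6.3 <= u.bf <= 8.0

    def test_determinism(self):
        a = generate_population("tetrode", 8, (6.3, 8.0), seed=3)
        b = generate_population("tetrode", 8, (6.3, 8.0), seed=3)
        assert a == b

    def test_unknown_geometry_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            generate_population("grid", 4, (1.0, 2.0), seed=0)

    def test_bf_outside_limits_rejected(self):
        with pytest.raises(ValueError):
            UnitSpec(unit_id="u", bf=60.0)


class TestRateModel:
    def test_on_bf_unit_driven_harder_than_off_bf(self, small_stimuli):
        """Oracle: closed-form drive integration from the rate model."""
        stim = small_stimuli.stimuli[0]  # low-frequency call (< 2.5 kHz)
        on = UnitSpec(unit_id="on", bf=1.0)
        off = UnitSpec(unit_id="off", bf=8.0)  # 3 octaves away
        d_on = stimulus_drive(stim, on, 1.0, small_stimuli.trial_length)
        d_off = stimulus_drive(stim, off, 1.0, small_stimuli.trial_length)
        assert d_on.mean() > 3.0 * d_off.mean()

    def test_zero_gain_reduces_to_homogeneous_poisson(self, small_stimuli):
        pop = generate_population("linear_double_shank", 1, (1.0, 2.0), seed=0,
                                  gain=0.0, baseline_rate=40.0)
        rec = simulate_responses(pop, small_stimuli, n_trials=60, seed=4)
        counts = [len(t) for sid in small_stimuli.ids
                  for t in rec.trains("mu00", sid)]
        expected = 40.0 * small_stimuli.trial_length
        lo = stats.poisson.ppf(0.005, expected * len(counts)) / len(counts)
        hi = stats.poisson.ppf(0.995, expected * len(counts)) / len(counts)
        assert lo <= np.mean(counts) <= hi

    def test_no_driven_spikes_before_onset(self, small_recording):
        """The first 20 ms carries spontaneous statistics only."""
        pre, total = 0, 0
        for sid in small_recording.stimuli.ids:
            for t in small_recording.trains("mu02", sid):
                pre += np.sum(t < 0.020)
                total += len(t)
        n_trials = small_recording.n_trials * small_recording.stimuli.n_voc
        expected = small_recording.population.units[2].baseline_rate * 0.020
        assert pre / n_trials == pytest.approx(expected, abs=3 * np.sqrt(
            expected / n_trials) + 0.2)

    def test_determinism(self, small_stimuli):
        pop = generate_population("linear_double_shank", 3, (0.5, 8.0), seed=3)
        a = simulate_responses(pop, small_stimuli, n_trials=3, seed=9)
        b = simulate_responses(pop, small_stimuli, n_trials=3, seed=9)
        for key in a.spike_times:
            for ta, tb in zip(a.spike_times[key], b.spike_times[key]):
                np.testing.assert_array_equal(ta, tb)

    def test_trial_count_conserved(self, small_recording):
        for key, trials in small_recording.spike_times.items():
            assert len(trials) == small_recording.n_trials

    def test_single_trial_rejected(self, small_stimuli):
        pop = generate_population("linear_double_shank", 2, (0.5, 8.0), seed=3)
        with pytest.raises(ValueError, match="n_trials"):
            simulate_responses(pop, small_stimuli, n_trials=1, seed=0)

    def test_psth_converges_to_rate_model(self):
        """Oracle: empirical PSTH over 600 trials vs the model's lambda."""
        tpl = [StimulusTemplate("a", 0.5, ((500.0, 2000.0),), am_rate=12.0),
               StimulusTemplate("b", 0.5, ((3000.0, 8000.0),))]
        ss = generate_vocalization_set(tpl, seed=2)
        ss = StimulusSet(ss.stimuli[:1], ss.trial_length, 70.0)
        pop = generate_population("linear_double_shank", 1, (1.0, 2.0), seed=0,
                                  latency_jitter_ms=0.0)
        u = pop.units[0]
        rec = simulate_responses(pop, ss, n_trials=600, seed=8)
        drive = stimulus_drive(ss.stimuli[0], u, 1.0, ss.trial_length)
        lam = u.baseline_rate + u.gain * drive  # spikes/s on the 1-ms grid
        edges = np.arange(0.0, 1.001, 0.010)
        hist = np.zeros(edges.size - 1)
        for t in rec.trains(u.unit_id, "a"):
            hist += np.histogram(t, bins=edges)[0]
        rate_hat = hist / 600 / 0.010
        lam_10ms = lam.reshape(-1, 10).mean(axis=1)
        se = np.sqrt(lam_10ms * 0.010 * 600) / 600 / 0.010
        assert np.all(np.abs(rate_hat - lam_10ms) <= 3 * se + 1e-9)


class TestVoltage:
    def test_pure_noise_sd_within_5pct(self, small_stimuli):
        pop = generate_population("linear_double_shank", 1, (1.0, 2.0), seed=0,
                                  baseline_rate=0.0, gain=0.0)
        ss = StimulusSet(small_stimuli.stimuli[:2], small_stimuli.trial_length)
        rec = simulate_responses(pop, ss, n_trials=2, seed=4)
        rec_v = synthesize_voltage(rec, noise_sd=2.5, seed=1)
        for trials in rec_v.voltage.values():
            for v in trials:
                assert v.std() == pytest.approx(2.5, rel=0.05)

    def test_noiseless_voltage_recovers_exact_spike_count(self, small_stimuli):
        """Oracle: the hand-placed ground-truth spike list."""
        from vocdisc import RecordingSet
        from vocdisc.preprocessing import bandpass, detect_spikes

        pop = generate_population("linear_double_shank", 1, (1.0, 2.0), seed=0)
        ss = StimulusSet(small_stimuli.stimuli[:1], small_stimuli.trial_length)
        # one spontaneous spike inside the 20-ms threshold window per trial,
        # the rest well separated (>= 10 ms apart)
        placed = [np.concatenate([[0.010], np.arange(0.05, 0.95, 0.040)]),
                  np.array([0.012, 0.1, 0.3, 0.31, 0.6])]
        rec = RecordingSet(population=pop, stimuli=ss, n_trials=2,
                           spike_times={("mu00", ss.ids[0]): placed})
        tpl = default_spike_template(amplitude=1.0)
        rec_v = synthesize_voltage(rec, waveform_template=tpl, noise_sd=0.02,
                                   seed=1)
        fs = rec_v.voltage_fs
        for k, v in enumerate(rec_v.voltage[("mu00", ss.ids[0])]):
            det = detect_spikes(bandpass(v, fs), fs)
            assert det.size == placed[k].size
            np.testing.assert_allclose(det, placed[k], atol=0.0005)

    def test_template_longer_than_5ms_rejected(self, small_recording):
        with pytest.raises(ValueError, match="5 ms"):
            synthesize_voltage(small_recording,
                               waveform_template=np.ones(200), noise_sd=1.0)


class TestHDF5Roundtrip:
    def test_spike_times_and_metadata_roundtrip(self, tmp_path,
                                                small_recording):
        path = tmp_path / "rec.h5"
        save_recordings(small_recording, path)
        loaded = load_recordings(path, small_recording.stimuli)
        assert loaded.n_trials == small_recording.n_trials
        assert loaded.population.geometry == "linear_double_shank"
        assert [u.unit_id for u in loaded.population.units] == \
            [u.unit_id for u in small_recording.population.units]
        for key in small_recording.spike_times:
            for ta, tb in zip(small_recording.spike_times[key],
                              loaded.spike_times[key]):
                np.testing.assert_allclose(ta, tb)

    def test_mismatched_stimuli_rejected(self, tmp_path, small_recording,
                                         full_stimuli):
        path = tmp_path / "rec.h5"
        save_recordings(small_recording, path)
        with pytest.raises(ValueError, match="stimulus set"):
            load_recordings(path, full_stimuli)
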