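"""Window sweeps, tonotopic profiles, BF estimation, aggregation."""

import numpy as np
import pandas as pd
import pytest

from vocdisc import (
    ClassificationResult,
    SegmentSpec,
    aggregate,
    estimate_best_frequency,
    generate_population,
    simulate_responses,
    simulate_tone_responses,
    spectral_match,
    third_octave_bins,
    tonotopic_profile,
    window_sweep,
)
from vocdisc.analysis import MatchScore, TonotopicProfile


def _fake_result(cc_per_voc, classes=("a", "b", "c"), sd=5.0):
    k = len(classes)
    cc_per_voc = np.asarray(cc_per_voc, dtype=float)
    conf = np.diag(cc_per_voc)
    return ClassificationResult(
        conf_mean=conf,
        cc_per_voc=cc_per_voc,
        cc=float(cc_per_voc.mean()),
        cc_sd=sd,
        classes=tuple(classes),
        fold_accuracy=np.full(10, float(cc_per_voc.mean())),
        fold_cc_per_voc=np.tile(cc_per_voc, (10, 1)),
    )


class TestWindowSweep:
    def test_consecutive_10ms_covers_trial_with_100_windows(
            self, small_recording, plan):
        res = window_sweep(small_recording,
                           small_recording.population.unit_ids[:2],
                           "consecutive-10ms", plan=plan)
        assert len(res.windows) == 100
        starts = [w.start for w in res.windows]
        np.testing.assert_allclose(np.diff(starts), 0.010)

    def test_post_onset_windows_beat_pre_onset(self, small_recording, plan):
        res = window_sweep(small_recording,
                           small_recording.population.unit_ids[:3],
                           "consecutive-100ms", plan=plan)
        pre = res.cc_per_window[0]  # first 100 ms: mostly pre-onset + onset
        post = res.cc_per_window[1:5].mean()
        assert post > pre - 10.0  # driven windows are at least as good

    def test_length_sweep_rejects_window_past_trial(self, small_recording,
                                                    plan):
        with pytest.raises(ValueError, match="past the trial"):
            window_sweep(small_recording, None, "length-sweep", plan=plan,
                         lengths_s=(0.9,), start_s=0.5)

    def test_cc_increases_with_segment_length(self, small_recording, plan):
        res = window_sweep(small_recording,
                           small_recording.population.unit_ids[:3],
                           "length-sweep", plan=plan,
                           lengths_s=(0.010, 0.100, 0.400), start_s=0.09)
        cc = res.cc_per_window
        sd = res.sd_per_window
        assert cc[1] >= cc[0] - (sd[0] + sd[1])
        assert cc[2] >= cc[1] - (sd[1] + sd[2])


class TestTonotopicProfile:
    def test_single_bin_mean(self):
        results = {f"u{i}": _fake_result([80.0 + 10 * i, 50.0, 50.0])
                   for i in range(3)}
        bfs = {f"u{i}": 1.0 for i in range(3)}  # all in one 1/3-oct bin
        prof = tonotopic_profile(results, bfs, "a")
        assert prof.cc_k.size == 1
        assert prof.cc_k[0] == pytest.approx(90.0)

    def test_propagated_se_matches_formula(self):
        results = {"u0": _fake_result([80.0, 50, 50], sd=5.0),
                   "u1": _fake_result([90.0, 50, 50], sd=5.0)}
        # identical fold diagonals -> zero across-fold SD -> zero SE
        bfs = {"u0": 2.0, "u1": 2.0}
        prof = tonotopic_profile(results, bfs, "a")
        assert prof.se[0] == pytest.approx(0.0, abs=1e-12)

    def test_unknown_vocalization_rejected(self):
        with pytest.raises(ValueError):
            tonotopic_profile({"u0": _fake_result([50, 50, 50])},
                              {"u0": 1.0}, "zzz")

    def test_third_octave_bins_anchor(self):
        edges = third_octave_bins()
        assert edges[0] == pytest.approx(0.5)
        np.testing.assert_allclose(edges[3] / edges[0], 2.0)  # 3 bins/octave


class TestSpectralMatch:
    def _profile(self, centers, values):
        edges = third_octave_bins()
        return TonotopicProfile(bf_bin_edges=edges,
                                bf_bin_centers=np.asarray(centers),
                                cc_k=np.asarray(values, dtype=float),
                                se=np.zeros(len(values)),
                                vocalization="x")

    @staticmethod
    def _spectrum(powers):
        """Synthetic spectrum placing the given powers in the 1.0- and
        2.0-kHz 1/3-octave profile bins (middle band falls between them)."""
        from vocdisc.stimuli import FrequencyBands, SpectralProfile

        bands = FrequencyBands(edges=np.array([0.9, 1.3, 1.9, 2.5]))
        bp = np.array([powers[0], 0.0, powers[1]], dtype=float)
        bp = bp / bp.sum()
        return SpectralProfile(band_power=bp,
                               log_band_power=np.log(np.maximum(bp, 1e-12)),
                               bands=bands)

    def test_identical_normalized_vectors_match_100(self):
        prof = self._profile([1.0, 2.0], [40.0, 60.0])
        spec = self._spectrum([0.4, 0.6])
        assert spectral_match(prof, spec).match_pct == pytest.approx(100.0)

    def test_disjoint_one_hot_vectors_match_0(self):
        prof = self._profile([1.0, 2.0], [1.0, 0.0])
        spec = self._spectrum([0.0, 1.0])
        assert spectral_match(prof, spec).match_pct == pytest.approx(
            0.0, abs=1e-9)

    def test_formula_oracle(self):
        prof = self._profile([1.0, 2.0], [3.0, 1.0])
        spec = self._spectrum([0.4, 0.6])
        p = np.array([0.75, 0.25])
        q = np.array([0.4, 0.6])
        expected = (1.0 - np.linalg.norm(p - q) / np.sqrt(2.0)) * 100.0
        assert spectral_match(prof, spec).match_pct == pytest.approx(
            expected, abs=1e-9)

    def test_match_score_bounds(self):
        with pytest.raises(ValueError):
            MatchScore(match_pct=120.0)


class TestBestFrequency:
    def test_parameter_recovery_from_tones(self):
        hits = 0
        for seed in range(10):
            pop = generate_population("tetrode", 1, (3.8, 4.2), seed=seed)
            pop_bf = pop.units[0].bf
            freqs, counts = simulate_tone_responses(pop, seed=seed)
            est = estimate_best_frequency(freqs, counts[pop.units[0].unit_id])
            step = np.log2(freqs[1] / freqs[0])
            hits += abs(np.log2(est / pop_bf)) <= 1.5 * step
        assert hits >= 9

    def test_single_candidate_frequency(self):
        assert estimate_best_frequency(np.array([2.0]), np.array([5])) == 2.0

    def test_tie_resolves_to_lower_frequency(self):
        freqs = np.array([1.0, 2.0, 4.0, 8.0])
        rates = np.array([3, 9, 9, 1])
        assert estimate_best_frequency(freqs, rates) == 2.0

    def test_untuned_unit_rejected(self):
        with pytest.raises(ValueError, match="untuned"):
            estimate_best_frequency(np.array([1.0, 2.0]), np.zeros(2))


class TestAggregate:
    def test_two_shank_error_propagation(self):
        df = pd.DataFrame({
            "position": ["p1", "p1"],
            "cc": [70.0, 80.0],
            "cc_sd": [2.0, 2.0],
        })
        out = aggregate(df, "position")
        assert out.loc[0, "cc"] == pytest.approx(75.0)
        assert out.loc[0, "se"] == pytest.approx(np.sqrt(8.0) / 2.0)

    def test_single_group_identity(self):
        df = pd.DataFrame({"animal": ["a1"], "cc": [66.0], "cc_sd": [3.0]})
        out = aggregate(df, "animal")
        assert out.loc[0, "cc"] == 66.0
        assert out.loc[0, "se"] == 3.0

    def test_intensity_ordering_and_monotonicity(self, am_band_stimuli):
        """CC rises with stimulus level (drive scales with amplitude)."""
        from vocdisc import CrossValPlan, StimulusSet, unit_classification

        rows = []
        pop = generate_population("linear_double_shank", 2, (0.5, 2.0), seed=3)
        for db in (30.0, 50.0, 70.0):
            ss = StimulusSet(am_band_stimuli.stimuli[:3],
                             am_band_stimuli.trial_length, db)
            rec = simulate_responses(pop, ss, n_trials=20, seed=6)
            res = unit_classification(rec, "mu00", SegmentSpec(0.1, 0.2),
                                      plan=CrossValPlan(seed=6))
            rows.append({"intensity_db": db, "cc": res.cc,
                         "cc_sd": res.cc_sd})
        out = aggregate(pd.DataFrame(rows), "intensity_db")
        assert list(out["intensity_db"]) == [30.0, 50.0, 70.0]
        assert out.loc[2, "cc"] >= out.loc[0, "cc"] - out.loc[0, "se"]

    def test_mixed_segments_rejected(self):
        df = pd.DataFrame({
            "shank": ["s1", "s1"],
            "cc": [50.0, 60.0],
            "cc_sd": [1.0, 1.0],
            "segment": ["0.1+0.1", "0.2+0.3"],
        })
        with pytest.raises(ValueError, match="segment"):
            aggregate(df, "shank")
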