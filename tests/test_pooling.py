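"""Pooling schemes: primitives, information content, ordering, curves."""

import numpy as np
import pytest

from vocdisc import (
    ClassifierSpec,
    CrossValPlan,
    PoolingSpec,
    SegmentSpec,
    crossval_classify,
    pool_add,
    pool_concatenate,
    pool_rates,
    pooling_curve,
    unit_classification,
)
from vocdisc.pooling import pooled_response_matrix, pooling_order
from vocdisc.preprocessing import BinnedSpikeTrain, epsp_convolve


class TestPrimitives:
    def test_concatenate_length(self, rng):
        traces = [rng.standard_normal(100) for _ in range(3)]
        assert pool_concatenate(traces).size == 300

    def test_concatenate_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="equal length"):
            pool_concatenate([rng.standard_normal(100),
                              rng.standard_normal(99)])

    def test_add_conserves_spikes(self, rng):
        a = BinnedSpikeTrain(counts=rng.poisson(0.12, 100))
        b = BinnedSpikeTrain(counts=rng.poisson(0.30, 100))
        summed = pool_add([a, b])
        assert summed.sum() == a.n_spikes + b.n_spikes

    def test_add_then_smooth_equals_sum_of_smoothed(self, rng):
        a = rng.poisson(0.2, 150)
        b = rng.poisson(0.2, 150)
        via_sum = epsp_convolve(BinnedSpikeTrain(counts=pool_add([a, b])))
        separate = (epsp_convolve(BinnedSpikeTrain(counts=a)).values
                    + epsp_convolve(BinnedSpikeTrain(counts=b)).values)
        np.testing.assert_allclose(via_sum.values, separate, atol=1e-9)

    def test_rate_vector_length_and_values(self):
        a = np.zeros(100, dtype=int)
        a[:10] = 1  # 10 spikes in 100 ms -> 100 sp/s
        b = np.zeros(100, dtype=int)
        vec = pool_rates([a, b])
        np.testing.assert_allclose(vec, [100.0, 0.0])

    def test_rate_window_must_be_100ms(self):
        with pytest.raises(ValueError, match="100"):
            pool_rates([np.zeros(50, dtype=int)], window_s=0.05)


class TestInformationContent:
    def test_concatenation_combines_complementary_units(self, rng):
        """Units informative about disjoint class subsets: pooled CC beats both.

        Unit A's traces separate classes 0-1 (identical for 2-3); unit B
        the reverse.  Concatenation must exceed both single units.
        """
        n_trials, n_bins = 20, 60
        tA = rng.standard_normal((2, n_bins))
        tB = rng.standard_normal((2, n_bins))
        rows_a, rows_b, labels = [], [], []
        for cls in range(4):
            for _ in range(n_trials):
                a = tA[cls] if cls < 2 else tA[0] * 0
                b = tB[cls - 2] if cls >= 2 else tB[0] * 0
                rows_a.append(a + 0.8 * rng.standard_normal(n_bins))
                rows_b.append(b + 0.8 * rng.standard_normal(n_bins))
                labels.append(cls)
        xa, xb = np.asarray(rows_a), np.asarray(rows_b)
        labels = np.asarray(labels)
        plan = CrossValPlan(seed=4)
        clf = ClassifierSpec("corr-template")
        cc_a = crossval_classify(xa, labels, clf, plan).cc
        cc_b = crossval_classify(xb, labels, clf, plan).cc
        cc_ab = crossval_classify(np.hstack([xa, xb]), labels, clf, plan).cc
        assert cc_ab > max(cc_a, cc_b)

    def test_addition_loses_unit_identity(self, rng):
        """Classes differing only in WHICH unit fires sum to identical trains."""
        n_trials, n_bins = 20, 50
        pattern = rng.poisson(1.0, n_bins)
        x_sum, labels = [], []
        for cls in range(2):
            for _ in range(n_trials):
                jitter = rng.poisson(0.3, n_bins)
                # class 0: unit A fires the pattern; class 1: unit B does
                a = pattern + jitter if cls == 0 else jitter
                b = jitter if cls == 0 else pattern + jitter
                x_sum.append(pool_add([a, b]).astype(float))
                labels.append(cls)
        res = crossval_classify(np.asarray(x_sum), np.asarray(labels),
                                ClassifierSpec("corr-template"),
                                CrossValPlan(seed=4))
        assert res.cc == pytest.approx(50.0, abs=15.0)

    def test_rate_pooling_blind_to_timing(self):
        """Equal-rate classes with distinct spike timing are chance for rates."""
        n_trials = 20
        x_rate, x_trace, labels = [], [], []
        rng = np.random.default_rng(7)
        for cls in range(2):
            for _ in range(n_trials):
                counts = np.zeros(100, dtype=int)
                # 10 spikes early (class 0) or late (class 1): same rate
                idx = (np.arange(10) if cls == 0 else 90 + np.arange(10))
                counts[idx] = 1
                x_rate.append(pool_rates([counts]))
                x_trace.append(counts.astype(float))
                labels.append(cls)
        labels = np.asarray(labels)
        res_rate = crossval_classify(np.asarray(x_rate), labels,
                                     ClassifierSpec("min-sq-rate"),
                                     CrossValPlan(seed=4))
        res_trace = crossval_classify(np.asarray(x_trace), labels,
                                      ClassifierSpec("corr-template"),
                                      CrossValPlan(seed=4))
        assert res_rate.cc == pytest.approx(50.0, abs=20.0)
        assert res_trace.cc == pytest.approx(100.0)


class TestPoolingCurve:
    def test_orders_are_deterministic_and_cover_all_units(self, small_recording):
        o1 = pooling_order(small_recording, "random", 0, seed=5)
        o2 = pooling_order(small_recording, "random", 0, seed=5)
        assert o1 == o2
        assert sorted(o1) == sorted(small_recording.population.unit_ids)
        g = pooling_order(small_recording, "gradual", 0, seed=5)
        assert g[0] == "mu00"  # lowest-BF seed unit
        g2 = pooling_order(small_recording, "gradual", 1, seed=5)
        assert g2[0] == "mu05"  # highest-BF end on the second iteration

    def test_n_comb_1_equals_single_unit_classification(self, small_recording,
                                                        plan):
        seg = SegmentSpec(0.1, 0.1)
        spec = PoolingSpec(method="concatenate", order="gradual", n_comb=2,
                           window=seg, seed=5)
        curve = pooling_curve(small_recording, spec, plan=plan)
        seed_unit = pooling_order(small_recording, "gradual", 0, seed=5)[0]
        single = unit_classification(small_recording, seed_unit, seg,
                                     plan=plan)
        assert curve.iteration_cc[0, 0] == pytest.approx(single.cc)

    def test_fixed_unit_permutation_leaves_result_unchanged(
            self, small_recording, plan):
        """A fixed coordinate permutation cannot change correlations."""
        seg = SegmentSpec(0.1, 0.1)
        ids = small_recording.population.unit_ids[:3]
        x1, lab = pooled_response_matrix(small_recording, ids, seg)
        x2, _ = pooled_response_matrix(small_recording, ids[::-1], seg)
        clf = ClassifierSpec("corr-template")
        r1 = crossval_classify(x1, lab, clf, plan)
        r2 = crossval_classify(x2, lab, clf, plan)
        np.testing.assert_allclose(r1.conf_mean, r2.conf_mean)

    def test_curve_shape_and_determinism(self, small_recording, plan):
        spec = PoolingSpec(method="add", order="random", n_comb=3, n_iter=2,
                           window=SegmentSpec(0.1, 0.1), seed=9)
        c1 = pooling_curve(small_recording, spec, plan=plan)
        c2 = pooling_curve(small_recording, spec, plan=plan)
        assert c1.cc.shape == (3,)
        np.testing.assert_array_equal(c1.cc, c2.cc)
        np.testing.assert_array_equal(c1.iteration_cc, c2.iteration_cc)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            PoolingSpec(method="average")
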