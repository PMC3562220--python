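import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mzmerge.errors import ComputationError, ConfigurationError
from mzmerge.feature_table import ReplicateDesign
from mzmerge.quality import (cv, evaluate_features, evaluate_samples,
                             filter_features, filter_samples, pid)

from .conftest import make_table

positive = st.floats(1e-3, 1e9, allow_nan=False)


class TestPid:
    def test_identity_is_zero(self):
        assert pid(123.4, 123.4) == 0.0

    def test_hand_case(self):
        # |100-300| = 200, mean = 200 -> 100%
        assert pid(100, 300) == pytest.approx(100.0)

    def test_zero_vs_positive_is_maximum(self):
        assert pid(0, 57.0) == pytest.approx(200.0)
        assert pid(57.0, 0) == pytest.approx(200.0)

    def test_both_zero_undefined(self):
        assert math.isnan(pid(0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pid(-1, 2)

    @settings(max_examples=100, deadline=None)
    @given(positive, positive)
    def test_symmetric_and_bounded(self, a, b):
        v = pid(a, b)
        assert v == pid(b, a)
        assert 0 <= v <= 200

    @settings(max_examples=50, deadline=None)
    @given(positive, positive, st.floats(1e-3, 1e3))
    def test_scale_invariant(self, a, b, k):
        assert pid(k * a, k * b) == pytest.approx(pid(a, b), rel=1e-9)


class TestCv:
    def test_constant_vector_zero(self):
        assert cv([7.7, 7.7, 7.7]) == 0.0

    def test_hand_case(self):
        # sd([2,4,6], ddof=1) = 2, mean = 4 -> 50%
        assert cv([2, 4, 6]) == pytest.approx(50.0)

    def test_single_value_precondition(self):
        with pytest.raises(ValueError):
            cv([5.0])

    def test_zero_mean_undefined(self):
        assert math.isnan(cv([0.0, 0.0]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(positive, min_size=2, max_size=8),
           st.floats(1e-3, 1e3))
    def test_scale_invariant(self, xs, k):
        assert cv([k * x for x in xs]) == pytest.approx(cv(xs), rel=1e-6)

    def test_translation_sensitive(self):
        assert cv([2, 4, 6]) != pytest.approx(cv([102, 104, 106]))


class TestEvaluateFeatures:
    def test_identical_duplicates_give_zero_median(self, duplicate_design,
                                                   profile_ids):
        vals = np.tile([[10.0, 10.0, 20.0, 20.0, 30.0, 30.0, 5.0, 5.0]], (3, 1))
        t = make_table([100, 200, 400], [1, 2, 3], vals, profile_ids)
        for q in evaluate_features(t, duplicate_design):
            assert q.metric_kind == "PID"
            assert q.median == 0.0

    def test_single_evaluable_sample(self, duplicate_design, profile_ids):
        row = [100.0, 300.0] + [np.nan] * 6
        t = make_table([100.0], [1.0], [row], profile_ids)
        (q,) = evaluate_features(t, duplicate_design)
        assert q.median == pytest.approx(100.0)
        assert set(q.per_sample) == {"S1"}

    def test_triplicates_use_cv(self):
        design = ReplicateDesign({"a": "S1", "b": "S1", "c": "S1"})
        t = make_table([100.0], [1.0], [[2.0, 4.0, 6.0]], ["a", "b", "c"])
        (q,) = evaluate_features(t, design)
        assert q.metric_kind == "CV"
        assert q.median == pytest.approx(50.0)

    def test_varying_replicate_counts_rejected(self):
        design = ReplicateDesign({"a": "S1", "b": "S1", "c": "S2",
                                  "d": "S2", "e": "S2"})
        t = make_table([100.0], [1.0], [np.ones(5)], list(design.assignments))
        with pytest.raises(ConfigurationError, match="S1"):
            evaluate_features(t, design)
        quals = evaluate_features(t, design, allow_mixed_replicates=True)
        assert quals[0].median == 0.0

    def test_no_evaluable_sample_flagged(self, duplicate_design, profile_ids):
        row = [np.nan, 1.0] * 4  # every sample has a missing replicate
        t = make_table([100.0], [1.0], [row], profile_ids)
        (q,) = evaluate_features(t, duplicate_design)
        assert q.summary is None and q.median is None

    def test_summary_ordering(self, duplicate_design, profile_ids):
        rng = np.random.default_rng(0)
        t = make_table([100.0], [1.0],
                       [rng.lognormal(10, 0.3, size=8)], profile_ids)
        (q,) = evaluate_features(t, duplicate_design)
        mn, q1, med, mean, q3, mx = q.summary
        assert mn <= q1 <= med <= q3 <= mx


def _pearson(x, y):
    # textbook sum formula, independent of numpy.corrcoef
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


class TestEvaluateSamples:
    def test_identical_replicates(self, duplicate_design, profile_ids):
        rng = np.random.default_rng(1)
        col = rng.lognormal(10, 1, size=5)
        inten = np.column_stack([col] * 8)
        t = make_table(np.linspace(100, 500, 5), np.arange(5), inten,
                       profile_ids)
        for q in evaluate_samples(t, duplicate_design):
            assert q.mean_pairwise_correlation == pytest.approx(1.0)

    def test_scaled_replicate_still_r_one(self):
        design = ReplicateDesign({"a": "S1", "b": "S1"})
        col = np.array([1.0, 5.0, 2.0, 9.0])
        t = make_table(np.linspace(100, 400, 4), np.arange(4),
                       np.column_stack([col, 2 * col]), ["a", "b"])
        (q,) = evaluate_samples(t, design)
        assert q.mean_pairwise_correlation == pytest.approx(1.0)

    def test_reversed_vectors_r_minus_one(self):
        design = ReplicateDesign({"a": "S1", "b": "S1"})
        t = make_table([100, 200, 300], [1, 2, 3],
                       np.column_stack([[1, 2, 3], [3, 2, 1]]), ["a", "b"])
        (q,) = evaluate_samples(t, design)
        assert q.mean_pairwise_correlation == pytest.approx(-1.0)

    def test_too_few_complete_features(self):
        design = ReplicateDesign({"a": "S1", "b": "S1"})
        inten = np.array([[1.0, 2.0], [np.nan, 3.0], [4.0, np.nan]])
        t = make_table([100, 200, 300], [1, 2, 3], inten, ["a", "b"])
        (q,) = evaluate_samples(t, design)
        assert q.mean_pairwise_correlation is None
        assert "complete" in q.reason

    def test_incomplete_features_excluded(self):
        # feature 1 is missing in an *unrelated* profile; completeness is
        # judged across all profiles of the table
        design = ReplicateDesign({"a": "S1", "b": "S1", "c": "S2", "d": "S2"})
        inten = np.array([
            [1.0, 1.1, 5.0, 5.0],
            [2.0, 9.9, np.nan, 1.0],   # excluded everywhere
            [3.0, 3.1, 6.0, 6.0],
            [4.0, 4.2, 7.0, 7.0],
        ])
        t = make_table([100, 200, 300, 400], [1, 2, 3, 4], inten,
                       ["a", "b", "c", "d"])
        (q1, q2) = evaluate_samples(t, design)
        assert q1.n_complete_features == 3
        expected = _pearson([1.0, 3.0, 4.0], [1.1, 3.1, 4.2])
        assert q1.mean_pairwise_correlation == pytest.approx(expected)

    def test_zero_variance_pair_excluded_and_counted(self):
        design = ReplicateDesign({"a": "S1", "b": "S1", "c": "S1"})
        inten = np.column_stack([[5.0, 5.0, 5.0],
                                 [1.0, 2.0, 3.0],
                                 [1.0, 2.5, 3.0]])
        t = make_table([100, 200, 300], [1, 2, 3], inten, ["a", "b", "c"])
        (q,) = evaluate_samples(t, design)
        assert q.n_undefined_pairs == 2  # both pairs with column "a"
        expected = _pearson([1.0, 2.0, 3.0], [1.0, 2.5, 3.0])
        assert q.mean_pairwise_correlation == pytest.approx(expected)

    def test_mean_over_pairs_matches_textbook_oracle(self, duplicate_design,
                                                     profile_ids):
        rng = np.random.default_rng(7)
        inten = rng.lognormal(10, 1, size=(10, 8))
        t = make_table(np.linspace(100, 800, 10), np.arange(10), inten,
                       profile_ids)
        for q, cols in zip(evaluate_samples(t, duplicate_design),
                           [(0, 1), (2, 3), (4, 5), (6, 7)]):
            expected = _pearson(inten[:, cols[0]].tolist(),
                                inten[:, cols[1]].tolist())
            assert q.mean_pairwise_correlation == pytest.approx(expected)


class TestFilters:
    def test_sample_filter_identity_when_all_good(self, small_table,
                                                  duplicate_design):
        sq = evaluate_samples(small_table, duplicate_design)
        t2, d2 = filter_samples(small_table, duplicate_design, sq, 0.7)
        assert t2.profile_ids == small_table.profile_ids

    def test_sample_filter_drops_bad_sample(self, profile_ids,
                                            duplicate_design):
        rng = np.random.default_rng(3)
        base = rng.lognormal(10, 1.0, size=10)  # feature-level structure
        inten = base[:, None] * rng.lognormal(0, 0.01, size=(10, 8))
        inten[:, 1] = rng.permutation(inten[:, 1])  # decorrelate S1
        t = make_table(np.linspace(100, 800, 10), np.arange(10), inten,
                       profile_ids)
        sq = evaluate_samples(t, duplicate_design)
        t2, d2 = filter_samples(t, duplicate_design, sq, 0.7)
        assert "S1_r1" not in t2.profile_ids and "S1_r2" not in t2.profile_ids
        assert set(d2.samples()) == {"S2", "S3", "S4"}

    def test_sample_filter_disabled(self, small_table, duplicate_design):
        t2, _ = filter_samples(small_table, duplicate_design, [], None)
        assert t2 is small_table

    def test_all_samples_dropped_raises(self, profile_ids, duplicate_design):
        rng = np.random.default_rng(4)
        inten = rng.lognormal(10, 1, size=(10, 8))
        t = make_table(np.linspace(100, 800, 10), np.arange(10), inten,
                       profile_ids)
        sq = evaluate_samples(t, duplicate_design)
        with pytest.raises(ComputationError):
            filter_samples(t, duplicate_design, sq, 1.1)

    def test_feature_filter_strict_inequality(self, profile_ids):
        # medians 0, 29.9, 30, 45 -> exactly two survive a strict 30 threshold
        from mzmerge.quality import FeatureQuality

        t = make_table([100, 200, 300, 400], [1, 2, 3, 4],
                       np.ones((4, 8)), profile_ids)
        quals = [
            FeatureQuality(i, "PID", {"S1": m}, (m, m, m, m, m, m))
            for i, m in enumerate([0.0, 29.9, 30.0, 45.0])
        ]
        kept = filter_features(t, quals, 30.0)
        assert kept.n_features == 2
        assert list(kept.mz) == [100.0, 200.0]

    def test_feature_filter_disabled_and_above_max(self, small_table,
                                                   duplicate_design):
        quals = evaluate_features(small_table, duplicate_design)
        assert filter_features(small_table, quals, None) is small_table
        # PID is bounded by 200, so 200 + eps keeps everything
        assert filter_features(small_table, quals,
                               200.001).n_features == small_table.n_features

    def test_all_features_filtered_gives_empty_table(self, small_table,
                                                     duplicate_design):
        quals = evaluate_features(small_table, duplicate_design)
        out = filter_features(small_table, quals, 1e-12)
        assert out.n_features == 0
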