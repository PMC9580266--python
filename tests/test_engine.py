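"""Unit and oracle tests for the ratio-metric core.

The brute-force oracles here enumerate candidate thresholds and sort keys
directly in pure Python, independently of the vectorised implementation.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ratiospec import engine
from ratiospec.engine import (
    Metric,
    MetricRanking,
    ScoringError,
    SelectionError,
    SplitConfig,
    StratificationError,
    TrainedMetric,
    classify_spectrum,
    enumerate_metrics,
    evaluate_predictions,
    largest_remainder_sizes,
    metric_value,
    pair_indices,
    rank_and_select,
    score_metric,
    split_dataset,
    train_metric,
)
from ratiospec.io import ConfigurationError

from conftest import make_dataset


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_rule_balanced_accuracy(ratios, labels, threshold, polarity):
    """Balanced accuracy of 'predict polarity when ratio > threshold'."""
    per_class = {}
    for cls in ("T", "NT"):
        hits = total = 0
        for r, y in zip(ratios, labels):
            if y != cls:
                continue
            total += 1
            if np.isnan(r):
                continue  # undefined counts as wrong
            pred = polarity if r > threshold else ("NT" if polarity == "T" else "T")
            hits += pred == cls
        per_class[cls] = hits / total
    return 0.5 * (per_class["T"] + per_class["NT"])


def oracle_train(ratios, labels):
    """Brute-force threshold fit: polarity = higher-mean class; threshold =
    lowest midpoint between adjacent distinct sorted defined ratios that
    maximises balanced accuracy (compared exactly, as the integer count
    hits_T * n_NT + hits_NT * n_T); fall back to the max ratio when no cut
    beats chance."""
    defined = [(r, y) for r, y in zip(ratios, labels) if not np.isnan(r)]
    t_vals = [r for r, y in defined if y == "T"]
    nt_vals = [r for r, y in defined if y == "NT"]
    if len(t_vals) < 2 or len(nt_vals) < 2:
        return None
    n_t, n_nt = len(t_vals), len(nt_vals)
    polarity = "T" if np.mean(t_vals) >= np.mean(nt_vals) else "NT"
    vals = sorted(r for r, _ in defined)
    best_thr, best_score = None, -1
    for a, b in zip(vals, vals[1:]):
        if b <= a:
            continue
        # hits counted from the value partition at the cut (<= a vs >= b)
        t_below = sum(1 for r in t_vals if r <= a)
        nt_below = sum(1 for r in nt_vals if r <= a)
        if polarity == "T":
            score = (n_t - t_below) * n_nt + nt_below * n_t
        else:
            score = t_below * n_nt + (n_nt - nt_below) * n_t
        if score > best_score:
            best_thr, best_score = 0.5 * (a + b), score
    if best_score < n_t * n_nt:  # nothing beats chance: predict all non-polarity
        best_thr = vals[-1]
    return best_thr, polarity, best_score / (2 * n_t * n_nt)


def oracle_rank(trained, n_top):
    """Exhaustive stable sort by (score desc, separation desc, canonical pair)."""
    return sorted(
        trained,
        key=lambda tm: (-tm.score, -tm.separation, tm.metric.w_num, tm.metric.w_den),
    )[:n_top]


def dataset_from_ratio_columns(num, den, labels):
    """Two-wavenumber dataset whose (0, 1) metric has ratio num/den."""
    return make_dataset(np.column_stack([num, den]), labels)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

class TestSplit:
    def test_exact_fraction_sizes_per_class(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.uniform(0.1, 1, (170, 4)), ["T"] * 100 + ["NT"] * 70)
        train, test, val = split_dataset(ds, SplitConfig(seed=3))
        for part, t_n, nt_n in [(train, 60, 42), (test, 20, 14), (val, 20, 14)]:
            assert (part.labels == "T").sum() == t_n
            assert (part.labels == "NT").sum() == nt_n

    def test_partition_property(self, toy_dataset):
        parts = split_dataset(toy_dataset, SplitConfig(seed=9))
        ids = sorted(s for p in parts for s in p.spectrum_ids)
        assert ids == sorted(toy_dataset.spectrum_ids)

    def test_seed_determinism(self, toy_dataset):
        a = split_dataset(toy_dataset, SplitConfig(seed=4))
        b = split_dataset(toy_dataset, SplitConfig(seed=4))
        c = split_dataset(toy_dataset, SplitConfig(seed=5))
        assert [list(p.spectrum_ids) for p in a] == [list(p.spectrum_ids) for p in b]
        assert [list(p.spectrum_ids) for p in a] != [list(p.spectrum_ids) for p in c]

    def test_group_by_patient_keeps_patients_whole(self):
        rng = np.random.default_rng(1)
        labels = ["T"] * 30 + ["NT"] * 30
        patients = [f"{l}{i // 6}" for i, l in enumerate(labels)]
        ds = make_dataset(rng.uniform(0.1, 1, (60, 4)), labels, patients=patients)
        parts = split_dataset(ds, SplitConfig(seed=2, group_by_patient=True))
        seen = {}
        for k, p in enumerate(parts):
            for pid in p.patient_ids:
                assert seen.setdefault(pid, k) == k

    def test_tiny_class_raises(self):
        ds = make_dataset(np.ones((4, 3)), ["T", "T", "NT", "NT"])
        with pytest.raises(StratificationError):
            split_dataset(ds, SplitConfig(seed=0))

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            SplitConfig(fractions=(0.5, 0.2, 0.2))

    @given(n=st.integers(3, 500))
    def test_largest_remainder_sums_to_n(self, n):
        sizes = largest_remainder_sizes(n, (0.6, 0.2, 0.2))
        assert sum(sizes) == n
        assert all(abs(s - n * f) <= 1 for s, f in zip(sizes, (0.6, 0.2, 0.2)))


# ---------------------------------------------------------------------------
# metric values and enumeration
# ---------------------------------------------------------------------------

class TestMetricValue:
    def test_enumeration_small_and_closed_form(self):
        ms = enumerate_metrics(3)
        assert [(m.w_num, m.w_den) for m in ms] == [(0, 1), (0, 2), (1, 2)]
        assert enumerate_metrics(2) == [Metric(0, 1)]
        ii, jj = pair_indices(317)
        assert ii.size == 317 * 316 // 2 == 50086
        with pytest.raises(ConfigurationError):
            pair_indices(1)

    def test_ratio_arithmetic(self):
        assert metric_value([0.8, 0.4], Metric(0, 1)) == pytest.approx(2.0)

    def test_denominator_guard_gives_nan(self):
        assert np.isnan(metric_value([0.8, 0.0], Metric(0, 1)))
        assert np.isnan(metric_value([0.8, 5e-7], Metric(0, 1), epsilon=1e-6))

    @given(
        a=st.floats(0.01, 10),
        b=st.floats(0.01, 10),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, a, b, c):
        spec = np.array([a, b])
        scaled = c * spec
        assert metric_value(scaled, Metric(0, 1)) == pytest.approx(
            metric_value(spec, Metric(0, 1)), rel=1e-9
        )

    def test_non_canonical_pair_rejected(self):
        with pytest.raises(ConfigurationError):
            Metric(3, 3)
        with pytest.raises(ConfigurationError):
            Metric(4, 2)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class TestTrainMetric:
    def test_separated_classes(self):
        ds = dataset_from_ratio_columns(
            [2.0, 2.1, 2.2, 1.0, 1.1, 1.2], [1.0] * 6, ["T", "T", "T", "NT", "NT", "NT"]
        )
        tm = train_metric(ds, Metric(0, 1))
        assert tm.polarity == "T"
        assert 1.2 < tm.threshold < 2.0
        assert score_metric(tm, ds) == pytest.approx(1.0)

    def test_identical_class_distributions_score_half(self):
        ds = dataset_from_ratio_columns(
            [1.0, 1.5, 2.0, 1.0, 1.5, 2.0], [1.0] * 6, ["T", "T", "T", "NT", "NT", "NT"]
        )
        tm = train_metric(ds, Metric(0, 1))
        assert score_metric(tm, ds) == pytest.approx(0.5)

    def test_guarded_denominators_make_metric_untrainable(self):
        ds = dataset_from_ratio_columns(
            [1.0] * 6, [0.0] * 6, ["T", "T", "T", "NT", "NT", "NT"]
        )
        tm = train_metric(ds, Metric(0, 1))
        assert not tm.trainable
        with pytest.raises(ScoringError):
            score_metric(tm, ds)

    @pytest.mark.parametrize("instance_seed", range(30))
    def test_threshold_matches_brute_force_oracle(self, instance_seed):
        rng = np.random.default_rng(100 + instance_seed)
        n = int(rng.integers(6, 60))
        labels = ["T"] * (n // 2) + ["NT"] * (n - n // 2)
        # mixture of smooth and heavily tied ratios
        num = rng.uniform(0.2, 2.0, n) + (0.3 * rng.integers(0, 2, n) if instance_seed % 3 else 0)
        if instance_seed % 2:
            num = np.round(num, 1)  # force ties
        den = np.full(n, 1.0)
        ds = dataset_from_ratio_columns(num, den, labels)
        tm = train_metric(ds, Metric(0, 1))
        expected = oracle_train(num / den, labels)
        assert tm.trainable
        thr, polarity, best_ba = expected
        assert tm.polarity == polarity
        assert tm.threshold == pytest.approx(thr)
        # spec invariant: training-set score of the fitted rule is >= 0.5
        assert score_metric(tm, ds) >= 0.5 - 1e-12
        assert tm.score == pytest.approx(max(best_ba, 0.5))

    def test_training_requires_both_classes(self):
        ds = dataset_from_ratio_columns([1.0, 2.0, 3.0], [1.0] * 3, ["T", "T", "T"])
        with pytest.raises(ScoringError):
            train_metric(ds, Metric(0, 1))


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

class TestScoreMetric:
    def test_partial_accuracy_formula(self):
        # all 4 T correct (ratio 2 > 1), half of 4 NT correct
        tm = TrainedMetric(Metric(0, 1), threshold=1.0, polarity="T")
        ds = dataset_from_ratio_columns(
            [2.0, 2.0, 2.0, 2.0, 0.5, 0.5, 2.0, 2.0],
            [1.0] * 8,
            ["T"] * 4 + ["NT"] * 4,
        )
        assert score_metric(tm, ds) == pytest.approx(0.75)

    def test_undefined_ratio_counts_as_misclassified(self):
        tm = TrainedMetric(Metric(0, 1), threshold=1.0, polarity="T")
        ds = dataset_from_ratio_columns(
            [2.0, 2.0, 0.5, 0.5], [1.0, 0.0, 1.0, 1.0], ["T", "T", "NT", "NT"]
        )
        # second T spectrum is undefined -> T accuracy 0.5, NT accuracy 1.0
        assert score_metric(tm, ds) == pytest.approx(0.75)

    def test_null_labels_score_near_half_on_average(self):
        # Monte-Carlo null: labels independent of ratios
        rng = np.random.default_rng(42)
        tm = TrainedMetric(Metric(0, 1), threshold=1.0, polarity="T")
        scores = []
        for _ in range(400):
            n = 60
            num = rng.uniform(0.2, 2.0, n)
            labels = np.array(["T"] * 30 + ["NT"] * 30, dtype=object)
            rng.shuffle(labels)
            scores.append(score_metric(tm, dataset_from_ratio_columns(num, np.ones(n), labels)))
        assert abs(np.mean(scores) - 0.5) < 0.03

    def test_single_class_test_set_rejected(self):
        tm = TrainedMetric(Metric(0, 1), threshold=1.0, polarity="T")
        ds = dataset_from_ratio_columns([2.0, 2.0], [1.0, 1.0], ["T", "T"])
        with pytest.raises(ScoringError):
            score_metric(tm, ds)


# ---------------------------------------------------------------------------
# ranking and voting
# ---------------------------------------------------------------------------

def _tm(i, j, score, sep=0.0):
    return TrainedMetric(Metric(i, j), threshold=1.0, polarity="T", separation=sep, score=score)


class TestRankAndSelect:
    def test_simple_ordering(self):
        ranking = rank_and_select([_tm(0, 1, 0.7), _tm(0, 2, 0.9), _tm(1, 2, 0.8)], 2)
        assert [(t.metric.w_num, t.metric.w_den) for t in ranking.metrics] == [(0, 2), (1, 2)]

    def test_all_ties_fall_back_to_canonical_order(self):
        tms = [_tm(1, 2, 0.8), _tm(0, 2, 0.8), _tm(0, 1, 0.8)]
        ranking = rank_and_select(tms, 3)
        assert [(t.metric.w_num, t.metric.w_den) for t in ranking.metrics] == [
            (0, 1), (0, 2), (1, 2),
        ]

    @pytest.mark.parametrize("instance_seed", range(10))
    def test_matches_exhaustive_sort_oracle(self, instance_seed):
        rng = np.random.default_rng(instance_seed)
        pairs = [(i, j) for i in range(12) for j in range(i + 1, 12)]
        rng.shuffle(pairs)
        tms = [
            _tm(i, j, float(rng.choice([0.6, 0.7, 0.8])), float(rng.choice([0.0, 1.0, 2.0])))
            for i, j in pairs[:50]
        ]
        got = rank_and_select(tms, 20).metrics
        expected = oracle_rank(tms, 20)
        assert [(t.metric, t.score, t.separation) for t in got] == [
            (t.metric, t.score, t.separation) for t in expected
        ]

    def test_selecting_too_many_raises(self):
        with pytest.raises(SelectionError):
            rank_and_select([_tm(0, 1, 0.9)], 2)


class TestClassify:
    def test_unanimous_vote(self):
        ranking = MetricRanking([_tm(0, 1, 0.9), _tm(0, 2, 0.8)], 2)
        assert classify_spectrum([2.0, 1.0, 1.0], ranking) == "T"

    def test_single_metric_polarity(self):
        tm = TrainedMetric(Metric(0, 1), threshold=1.5, polarity="T", score=0.9)
        assert classify_spectrum([2.0, 1.0], MetricRanking([tm], 1)) == "T"
        assert classify_spectrum([1.0, 1.0], MetricRanking([tm], 1)) == "NT"

    def test_equal_weight_tie_goes_to_nt(self):
        up = TrainedMetric(Metric(0, 1), threshold=1.0, polarity="T", score=0.8)
        down = TrainedMetric(Metric(0, 2), threshold=10.0, polarity="T", score=0.8)
        # first votes T (2 > 1), second votes NT (2 < 10)
        assert classify_spectrum([2.0, 1.0, 1.0], MetricRanking([up, down], 2)) == "NT"

    def test_all_abstain_is_unclassifiable(self):
        tm = TrainedMetric(Metric(0, 1), threshold=1.0, polarity="T", score=0.9)
        assert classify_spectrum([1.0, 0.0], MetricRanking([tm], 1)) == engine.UNCLASSIFIABLE

    def test_weighted_vote_beats_count(self):
        strong = TrainedMetric(Metric(0, 1), threshold=1.0, polarity="T", score=0.99)
        weak1 = TrainedMetric(Metric(0, 2), threshold=10.0, polarity="T", score=0.4)
        weak2 = TrainedMetric(Metric(1, 2), threshold=10.0, polarity="T", score=0.4)
        ranking = MetricRanking([strong, weak1, weak2], 3)
        assert classify_spectrum([2.0, 1.0, 1.0], ranking) == "T"

    @given(c=st.floats(1e-3, 1e3))
    def test_classification_scale_invariant(self, c):
        tms = [
            TrainedMetric(Metric(0, 1), threshold=1.3, polarity="T", score=0.9),
            TrainedMetric(Metric(1, 2), threshold=0.7, polarity="NT", score=0.7),
        ]
        ranking = MetricRanking(tms, 2)
        spec = np.array([1.5, 1.0, 0.8])
        assert classify_spectrum(spec, ranking) == classify_spectrum(c * spec, ranking)


class TestEvaluate:
    def test_perfect(self):
        assert evaluate_predictions(["T", "NT"], ["T", "NT"]) == (1.0, 1.0, 1.0)

    def test_confusion_formulae(self):
        pred = ["T"] * 8 + ["NT"] * 2 + ["NT"] * 7 + ["T"] * 3
        truth = ["T"] * 10 + ["NT"] * 10
        sens, spec, prec = evaluate_predictions(pred, truth)
        assert sens == pytest.approx(0.8)
        assert spec == pytest.approx(0.7)
        assert prec == pytest.approx(8 / 11)

    def test_all_nt_precision_undefined(self):
        sens, spec, prec = evaluate_predictions(["NT"] * 4, ["T", "T", "NT", "NT"])
        assert (sens, spec) == (0.0, 1.0)
        assert np.isnan(prec)

    def test_unclassifiable_counts_as_wrong(self):
        sens, spec, prec = evaluate_predictions(
            ["", "T", "", "NT"], ["T", "T", "NT", "NT"]
        )
        assert sens == pytest.approx(0.5)
        assert spec == pytest.approx(0.5)
        assert prec == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_predictions(["T"], ["T", "NT"])


# ---------------------------------------------------------------------------
# batch path vs per-metric path
# ---------------------------------------------------------------------------

class TestBatchAgreement:
    def test_batch_and_scalar_paths_agree(self, toy_dataset):
        ii, jj = pair_indices(toy_dataset.n_wavenumbers)
        fit = engine.train_metrics_batch(toy_dataset, ii, jj)
        scores = engine.score_metrics_batch(
            toy_dataset, ii, jj, fit["threshold"], fit["polarity_T"]
        )
        for k in range(0, ii.size, 5):
            tm = train_metric(toy_dataset, Metric(int(ii[k]), int(jj[k])))
            assert tm.trainable == bool(fit["trainable"][k])
            if tm.trainable:
                assert tm.threshold == pytest.approx(float(fit["threshold"][k]))
                assert (tm.polarity == "T") == bool(fit["polarity_T"][k])
                assert score_metric(tm, toy_dataset) == pytest.approx(float(scores[k]))
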