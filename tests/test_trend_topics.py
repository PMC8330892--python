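"""Trimmed means, moving averages, trend series, and topic summaries."""

import math
from datetime import date, timedelta

import numpy as np
import pytest

from depsignal import (aggregate_trend, compare_groups_trend, dominant_topic,
                       fit_topics, moving_average, topic_frequencies, trimmed_mean)
from depsignal.preprocess_chunk import TweetChunk
from depsignal.trend_topics import estimate_changepoint


def _oracle_trim_mean(values, trim):
    """Independent oracle: repeatedly discard the current min and max."""
    vals = list(values)
    n = len(vals)
    k = math.ceil(trim * n) if (n >= 3 and trim > 0) else 0
    k = min(k, (n - 1) // 2)
    for _ in range(k):
        vals.remove(max(vals))
        vals.remove(min(vals))
    return sum(vals) / len(vals)


class TestTrimmedMean:
    def test_ceiling_rule_example(self):
        # n=5, trim=0.10 -> ceil(0.5)=1 dropped from each tail
        assert trimmed_mean([0, 0.5, 0.5, 0.5, 1], 0.10) == pytest.approx(0.5)

    def test_zero_trim_is_plain_mean(self):
        rng = np.random.default_rng(0)
        v = rng.random(17)
        assert trimmed_mean(v, 0.0) == pytest.approx(v.mean(), abs=1e-12)

    def test_matches_oracle_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(1, 30))
            v = rng.random(n)
            trim = float(rng.choice([0.0, 0.05, 0.1, 0.25]))
            assert trimmed_mean(v, trim) == pytest.approx(
                _oracle_trim_mean(v, trim), abs=1e-10)

    def test_within_min_max(self):
        rng = np.random.default_rng(2)
        v = rng.random(11)
        t = trimmed_mean(v, 0.1)
        assert v.min() <= t <= v.max()

    def test_invalid_trim(self):
        with pytest.raises(ValueError):
            trimmed_mean([1, 2, 3], 0.5)


class TestMovingAverage:
    def test_constant_series_preserved(self):
        out = moving_average([3.0] * 10, 5)
        assert np.allclose(out, 3.0)

    def test_linear_ramp_exact_in_interior(self):
        ramp = np.arange(20, dtype=float)
        out = moving_average(ramp, 5)
        assert np.allclose(out[2:-2], ramp[2:-2])

    def test_matches_window_oracle(self):
        rng = np.random.default_rng(3)
        v = rng.random(30)
        out = moving_average(v, 5)
        for i in range(30):
            lo, hi = max(0, i - 2), min(30, i + 3)
            assert out[i] == pytest.approx(np.mean(v[lo:hi]), abs=1e-12)

    def test_nan_gap_not_interpolated(self):
        v = [1.0, np.nan, 3.0, 4.0, 5.0]
        out = moving_average(v, 3)
        assert np.isnan(out[1])
        assert out[2] == pytest.approx(np.mean([3.0, 4.0]))


class TestAggregateTrend:
    def _series(self, dates_scores, **kw):
        d, s = zip(*dates_scores)
        return aggregate_trend(list(d), list(s), origin=date(2020, 1, 1), **kw)

    def test_constant_scores_give_constant_series(self):
        data = [(date(2020, 1, 1) + timedelta(days=i), 0.4) for i in range(30)]
        series = self._series(data)
        assert np.allclose(series.raw(), 0.4)
        assert np.allclose(series.smoothed(), 0.4)

    def test_bins_contiguous_from_origin(self):
        data = [(date(2020, 1, 1) + timedelta(days=i), 0.5) for i in range(0, 30, 2)]
        series = self._series(data, bin_days=3)
        starts = [b.bin_start for b in series.bins]
        assert starts == [date(2020, 1, 1) + timedelta(days=3 * i)
                          for i in range(len(starts))]
        assert len(series.smoothed()) == len(series.raw())

    def test_empty_bin_stays_missing(self):
        data = ([(date(2020, 1, 1), 0.5)] * 4
                + [(date(2020, 1, 10), 0.7)] * 4)  # bins 1 and 2 empty
        series = self._series(data, bin_days=3)
        assert np.isnan(series.bins[1].raw_mean)
        assert np.isnan(series.bins[1].smoothed_mean)
        assert series.bins[0].n_chunks == 4

    def test_global_trim_scope(self):
        data = [(date(2020, 1, 1), v) for v in (0.0, 0.5, 0.5, 0.5, 1.0)]
        series = self._series(data, trim_scope="global")
        assert series.bins[0].raw_mean == pytest.approx(0.5)

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            aggregate_trend([date(2020, 1, 1)], [0.1, 0.2], origin=date(2020, 1, 1))


class TestCompareTrends:
    def _mk(self, values):
        return aggregate_trend(
            [date(2020, 1, 1) + timedelta(days=3 * i) for i in range(len(values))],
            values, origin=date(2020, 1, 1), trim=0.0, ma_window=1)

    def test_identical_series(self):
        a = self._mk([0.1, 0.4, 0.2, 0.6, 0.5])
        rep = compare_groups_trend(a, a)
        assert rep["rank_correlation"] == pytest.approx(1.0)
        assert np.allclose(rep["per_bin_diff"], 0.0)

    def test_constant_shift(self):
        vals = [0.1, 0.4, 0.2, 0.6, 0.5]
        a = self._mk(vals)
        b = self._mk([v + 0.2 for v in vals])
        rep = compare_groups_trend(b, a)
        assert rep["rank_correlation"] == pytest.approx(1.0)
        assert np.allclose(rep["per_bin_diff"], 0.2)

    def test_rank_correlation_matches_manual_oracle(self):
        rng = np.random.default_rng(4)
        x, y = rng.random(40), rng.random(40)
        a, b = self._mk(list(x)), self._mk(list(y))
        rep = compare_groups_trend(a, b)
        # oracle: Pearson correlation of the rank vectors
        rx = np.argsort(np.argsort(a.smoothed()))
        ry = np.argsort(np.argsort(b.smoothed()))
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rep["rank_correlation"] == pytest.approx(oracle, abs=1e-10)

    def test_binning_mismatch_errors(self):
        a = self._mk([0.1, 0.2, 0.3])
        b = self._mk([0.1, 0.2])
        with pytest.raises(ValueError):
            compare_groups_trend(a, b)


def test_estimate_changepoint_on_clean_step():
    vals = [0.2] * 20 + [0.8] * 20
    series = aggregate_trend(
        [date(2020, 1, 1) + timedelta(days=3 * i) for i in range(40)],
        vals, origin=date(2020, 1, 1), trim=0.0, ma_window=1)
    assert estimate_changepoint(series) == date(2020, 1, 1) + timedelta(days=60)


class TestTopics:
    def _chunks(self, texts, group="case", start=date(2020, 1, 1)):
        return [TweetChunk(f"c{i}", f"u{i}", group, t, len(t.split()),
                           [f"t{i}"], start + timedelta(days=i))
                for i, t in enumerate(texts)]

    def test_fewer_documents_than_k_errors(self):
        with pytest.raises(ValueError):
            fit_topics(["a b", "c d"], k=5)

    def test_disjoint_vocabulary_recovery(self):
        rng = np.random.default_rng(5)
        vocab_a = [f"alpha{i}" for i in range(25)]
        vocab_b = [f"beta{i}" for i in range(25)]
        texts, truth = [], []
        for i in range(120):
            vocab = vocab_a if i % 2 == 0 else vocab_b
            truth.append(i % 2)
            texts.append(" ".join(rng.choice(vocab, size=40)))
        model = fit_topics(texts, k=2, seed=0)
        assigned = dominant_topic(model, texts)
        # map recovered topics to generating vocabulary by majority
        truth = np.array(truth)
        agreement = max(np.mean(assigned == truth), np.mean(assigned == 1 - truth))
        assert agreement > 0.9

    def test_partition_counts_sum_to_totals(self):
        rng = np.random.default_rng(6)
        texts = [" ".join(rng.choice([f"w{i}" for i in range(30)], size=20))
                 for _ in range(40)]
        chunks = (self._chunks(texts[:20], group="case")
                  + self._chunks(texts[20:], group="control"))
        model = fit_topics(texts, k=3, seed=1)
        cut = date(2020, 1, 10)
        before, after = topic_frequencies(model, chunks, cut)
        for group in ("case", "control"):
            n_before = sum(before.counts.get(group, {}).values())
            n_after = sum(after.counts.get(group, {}).values())
            total = sum(1 for c in chunks if c.label == group)
            assert n_before + n_after == total
        # partition respects the cut date
        assert all(c.chunk_date < cut or c.chunk_date >= cut for c in chunks)

    def test_dominant_topic_deterministic(self):
        rng = np.random.default_rng(7)
        texts = [" ".join(rng.choice([f"w{i}" for i in range(30)], size=20))
                 for _ in range(30)]
        m1 = fit_topics(texts, k=3, seed=9)
        m2 = fit_topics(texts, k=3, seed=9)
        assert np.array_equal(dominant_topic(m1, texts), dominant_topic(m2, texts))
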