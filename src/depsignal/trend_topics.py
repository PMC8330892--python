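"""Group-level depression trend curves and topic summaries.

Dated chunk scores are assigned to fixed-width time bins from an origin
date (default 3 days), robustified by trimming the upper and lower fraction
of each bin's scores (ceil(trim * n) dropped from each tail; no trimming
below n = 3), averaged, and smoothed with a centered moving average whose
window shrinks at the series edges. Empty bins stay missing - no
interpolation - and a missing raw bin stays missing after smoothing.

Topical content is summarized with an off-the-shelf variational LDA
(k = 5 topics by default): each chunk's dominant topic is the argmax of its
topic weights (ties break to the lowest topic id), and dominant-topic
frequencies are counted per group before and after a cut date.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.feature_extraction.text import CountVectorizer

from .preprocess_chunk import TweetChunk


# --------------------------------------------------------------------------
# Trend aggregation
# --------------------------------------------------------------------------

def trimmed_mean(values, trim: float = 0.10) -> float:
    """Mean after dropping ceil(trim*n) values from each tail; below n=3 no
    trimming is applied. trim must lie in [0, 0.5)."""
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must lie in [0, 0.5)")
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        return math.nan
    k = math.ceil(trim * n) if (n >= 3 and trim > 0) else 0
    if 2 * k >= n:
        k = (n - 1) // 2
    return float(v[k:n - k].mean())


def moving_average(values, window: int = 5) -> np.ndarray:
    """Centered moving average with the window shrunk at the edges.

    NaNs are skipped inside the window; a NaN input bin stays NaN in the
    output (gaps are not interpolated).
    """
    v = np.asarray(values, dtype=float)
    half = window // 2
    out = np.full_like(v, np.nan)
    for i in range(len(v)):
        if np.isnan(v[i]):
            continue
        lo, hi = max(0, i - half), min(len(v), i + half + 1)
        win = v[lo:hi]
        win = win[~np.isnan(win)]
        if len(win):
            out[i] = win.mean()
    return out


@dataclass
class TrendBin:
    bin_start: date
    raw_mean: float
    smoothed_mean: float
    n_chunks: int


@dataclass
class TrendSeries:
    group_id: str
    origin: date
    bin_days: int
    trim: float
    ma_window: int
    bins: list[TrendBin]

    def raw(self) -> np.ndarray:
        return np.array([b.raw_mean for b in self.bins])

    def smoothed(self) -> np.ndarray:
        return np.array([b.smoothed_mean for b in self.bins])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_start": [b.bin_start for b in self.bins],
             "group": self.group_id,
             "raw_mean": self.raw(), "smoothed_mean": self.smoothed(),
             "n_chunks": [b.n_chunks for b in self.bins]})


def aggregate_trend(dates, scores, origin: date, end: date | None = None,
                    bin_days: int = 3, trim: float = 0.10, ma_window: int = 5,
                    group_id: str = "", trim_scope: str = "bin") -> TrendSeries:
    """Bin dated scores from ``origin`` at ``bin_days`` spacing, trim, mean,
    and smooth.

    trim_scope="bin" (default) trims within each bin; "global" drops the
    pooled upper/lower tails once before binning.
    """
    dates = list(dates)
    scores = np.asarray(scores, dtype=float)
    if len(dates) != len(scores):
        raise ValueError("dates and scores must align")
    if trim_scope not in ("bin", "global"):
        raise ValueError("trim_scope must be 'bin' or 'global'")
    if any(d is None for d in dates):
        raise ValueError("every score needs a chunk date")
    if end is None:
        end = max(dates)

    if trim_scope == "global" and trim > 0 and len(scores) >= 3:
        k = math.ceil(trim * len(scores))
        order = np.argsort(scores, kind="stable")
        keep = set(order[k:len(scores) - k].tolist())
        dates = [d for i, d in enumerate(dates) if i in keep]
        scores = scores[sorted(keep)]

    n_bins = (end - origin).days // bin_days + 1
    per_bin: list[list[float]] = [[] for _ in range(n_bins)]
    for d, s in zip(dates, scores):
        idx = (d - origin).days // bin_days
        if 0 <= idx < n_bins:
            per_bin[idx].append(float(s))

    raw = np.array([
        trimmed_mean(vals, trim) if (vals and trim_scope == "bin")
        else (float(np.mean(vals)) if vals else math.nan)
        for vals in per_bin])
    smooth = moving_average(raw, ma_window)
    bins = [TrendBin(origin + timedelta(days=i * bin_days), raw[i], smooth[i],
                     len(per_bin[i])) for i in range(n_bins)]
    return TrendSeries(group_id, origin, bin_days, trim, ma_window, bins)


def trend_by_group(chunks: list[TweetChunk], scores, origin: date,
                   end: date | None = None, **kwargs) -> dict[str, TrendSeries]:
    by_group: dict[str, tuple[list, list]] = {}
    for c, s in zip(chunks, scores):
        d, sc = by_group.setdefault(c.label, ([], []))
        d.append(c.chunk_date)
        sc.append(s)
    return {g: aggregate_trend(d, s, origin, end=end, group_id=g, **kwargs)
            for g, (d, s) in sorted(by_group.items())}


def compare_groups_trend(series_a: TrendSeries, series_b: TrendSeries) -> dict:
    """Per-bin difference and rank correlation between two smoothed series
    on the same binning."""
    if (series_a.origin != series_b.origin or series_a.bin_days != series_b.bin_days
            or len(series_a.bins) != len(series_b.bins)):
        raise ValueError("series are on different binnings")
    a, b = series_a.smoothed(), series_b.smoothed()
    diff = a - b
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() >= 2 and np.ptp(a[ok]) > 0 and np.ptp(b[ok]) > 0:
        rho = float(stats.spearmanr(a[ok], b[ok]).statistic)
    else:
        rho = 1.0 if ok.sum() and np.allclose(a[ok], b[ok]) else math.nan
    return {"per_bin_diff": diff, "rank_correlation": rho, "n_bins": len(a)}


def estimate_changepoint(series: TrendSeries) -> date:
    """Location of the maximal first difference of the smoothed series."""
    s = series.smoothed()
    d = np.diff(s)
    idx = int(np.nanargmax(d)) + 1
    return series.bins[idx].bin_start


# --------------------------------------------------------------------------
# Topics
# --------------------------------------------------------------------------

@dataclass
class TopicModel:
    vectorizer: CountVectorizer
    lda: LatentDirichletAllocation
    k: int

    def weights(self, texts: list[str]) -> np.ndarray:
        return self.lda.transform(self.vectorizer.transform(texts))

    def top_words(self, n: int = 10) -> list[list[str]]:
        vocab = np.asarray(self.vectorizer.get_feature_names_out())
        return [vocab[np.argsort(comp)[::-1][:n]].tolist()
                for comp in self.lda.components_]


@dataclass
class TopicSummary:
    period: str
    counts: dict[str, dict[int, int]]  # group -> topic_id -> chunk count
    keywords: list[list[str]]


def fit_topics(texts: list[str], k: int = 5, seed: int = 0) -> TopicModel:
    if len(texts) < k:
        raise ValueError(f"need at least k={k} documents, got {len(texts)}")
    vec = CountVectorizer()
    X = vec.fit_transform(texts)
    lda = LatentDirichletAllocation(n_components=k, random_state=seed,
                                    max_iter=15)
    lda.fit(X)
    return TopicModel(vec, lda, k)


def dominant_topic(model: TopicModel, texts: list[str]) -> np.ndarray:
    """Argmax-weight topic per document; ties resolve to the lowest id."""
    return np.argmax(model.weights(texts), axis=1)


def topic_frequencies(model: TopicModel, chunks: list[TweetChunk],
                      cut_date: date, top_words: int = 10
                      ) -> tuple[TopicSummary, TopicSummary]:
    """Dominant-topic counts per group before (< cut_date) and after
    (>= cut_date)."""
    if any(c.chunk_date is None for c in chunks):
        raise ValueError("chunks must carry dates (monitoring mode)")
    topics = dominant_topic(model, [c.text for c in chunks])
    keywords = model.top_words(top_words)
    summaries = []
    for period, keep in (("before", lambda c: c.chunk_date < cut_date),
                         ("after", lambda c: c.chunk_date >= cut_date)):
        counts: dict[str, dict[int, int]] = {}
        for c, t in zip(chunks, topics):
            if keep(c):
                g = counts.setdefault(c.label, {k: 0 for k in range(model.k)})
                g[int(t)] += 1
        summaries.append(TopicSummary(period, counts, keywords))
    return summaries[0], summaries[1]
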