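"""End-to-end pipeline runs: staged execution, manifests, and the default
synthetic benchmark.

Stages run in the order simulate -> screen -> chunk -> featurize -> train ->
score -> fuse -> trend -> topics, exchanging plain-text artifacts (JSON-lines
corpora and chunks, CSV/TSV tables) inside one output directory. A manifest
records per-stage parameters, derived seeds, artifact checksums and record
counts, so retention fractions and data-flow numbers are visible for every
run. One global seed deterministically derives every stage seed.

The module also hosts the in-memory benchmark drivers shared by the test
suite and the acceptance script: `run_benchmark` (screening, chunk and user
classification, fusion, importance on one seeded synthetic cohort),
`run_trend_benchmark` (trend recovery after an injected changepoint) and
`run_null_calibration` (type-I-error rate of the group-difference test).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats

from .records import CASE, CONTROL, UserRecord, read_corpus, write_corpus
from .synthetic_corpus import SimConfig, default_config, generate_corpus, has_disclosure, null_config
from .cohort_screener import PatternSet, ScreeningResult, compile_patterns, screen_corpus
from .preprocess_chunk import (SplitAssignment, TweetChunk, chunk_corpus,
                               stratified_split)
from .feature_extraction import (CategoryLexicon, assemble_user_features,
                                 complete_cases, compare_groups, features_table)
from .chunk_scoring import (NgramLogisticScorer, TrainConfig, evaluate,
                            train_scorer, user_scores_by_id)
from .fusion_importance import (ALL_GROUPS, FIVE_GROUPS, IMPORTANCE_GROUPS,
                                FusionSpec, ablation_table, fit_fusion,
                                permutation_importance, predict_scores)
from .trend_topics import (aggregate_trend, estimate_changepoint, fit_topics,
                           topic_frequencies, trend_by_group)

STAGES = ("simulate", "screen", "chunk", "featurize", "train", "score",
          "fuse", "trend", "topics")


def stage_seed(global_seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([global_seed, idx]).generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunConfig:
    """Stage parameters; the numeric defaults are the reference analysis
    values (250-word chunks, 500-user test set, 0.5 threshold, 3-day bins,
    10% trim, 5-bin moving average, 10 importance repeats, 5 topics)."""

    out_dir: str = "runs/default"
    sim: SimConfig = field(default_factory=default_config)
    patterns_path: str | None = None
    lexicon_path: str | None = None
    max_words: int = 250
    test_n: int = 500
    train_sizes: tuple = (1000, 2000, None)
    threshold: float = 0.5
    bin_days: int = 3
    trim: float = 0.10
    ma_window: int = 5
    importance_repeats: int = 10
    k_topics: int = 5
    fusion_family: str = "max_margin"
    trend_origin: date | None = None
    cut_date: date | None = None
    seed: int = 0

    def path(self, name: str) -> Path:
        return Path(self.out_dir) / name


# --------------------------------------------------------------------------
# Path-based stages
# --------------------------------------------------------------------------

def _require(cfg: RunConfig, name: str, producer: str) -> Path:
    p = cfg.path(name)
    if not p.exists():
        raise FileNotFoundError(f"missing {p}; run {producer} first")
    return p


def _read_chunks(path: Path) -> list[TweetChunk]:
    return [TweetChunk.from_dict(json.loads(l))
            for l in path.read_text().splitlines() if l.strip()]


def _write_chunks(chunks: list[TweetChunk], path: Path) -> None:
    path.write_text("".join(json.dumps(c.to_dict(), sort_keys=True) + "\n"
                            for c in chunks))


def stage_simulate(cfg: RunConfig) -> dict:
    sim = cfg.sim
    corpus = generate_corpus(sim)
    write_corpus(corpus, cfg.path("corpus.jsonl"))
    return {"users": len(corpus),
            "cases": sum(u.group == CASE for u in corpus)}


def stage_screen(cfg: RunConfig) -> dict:
    corpus = read_corpus(_require(cfg, "corpus.jsonl", "simulate"))
    pattern_set = (PatternSet.from_json(cfg.patterns_path)
                   if cfg.patterns_path else PatternSet.default())
    results = screen_corpus(corpus, compile_patterns(pattern_set))
    cfg.path("screening.jsonl").write_text(
        "".join(json.dumps(r.to_dict(), sort_keys=True) + "\n" for r in results))
    return {"screened": len(results),
            "cases_flagged": sum(r.is_case for r in results)}


def _read_screening(path: Path) -> list[dict]:
    return [json.loads(l) for l in path.read_text().splitlines() if l.strip()]


def stage_chunk(cfg: RunConfig) -> dict:
    corpus = read_corpus(_require(cfg, "corpus.jsonl", "simulate"))
    screening = _read_screening(_require(cfg, "screening.jsonl", "screen"))
    identifying = {tid for r in screening for tid in r["identifying_tweet_ids"]}
    chunks = chunk_corpus(corpus, max_words=cfg.max_words,
                          mode="classification", identifying_ids=identifying)
    monitor = chunk_corpus(corpus, max_words=cfg.max_words,
                           mode="monitoring", identifying_ids=identifying)
    _write_chunks(chunks, cfg.path("chunks.jsonl"))
    _write_chunks(monitor, cfg.path("chunks_monitoring.jsonl"))
    split = stratified_split(corpus, test_n=cfg.test_n,
                             train_sizes=list(cfg.train_sizes),
                             seed=stage_seed(cfg.seed, "chunk"))
    cfg.path("split.json").write_text(json.dumps(split.to_dict(), indent=2))
    return {"chunks": len(chunks), "monitoring_chunks": len(monitor),
            "identifying_tweets_dropped": len(identifying),
            "chunks_per_user": round(len(chunks) / len(corpus), 2)}


def stage_featurize(cfg: RunConfig) -> dict:
    corpus = read_corpus(_require(cfg, "corpus.jsonl", "simulate"))
    chunks = _read_chunks(_require(cfg, "chunks.jsonl", "chunk"))
    lexicon = (CategoryLexicon.from_json(cfg.lexicon_path)
               if cfg.lexicon_path else CategoryLexicon.default())
    text_by_user: dict[str, list[str]] = {}
    for c in chunks:
        text_by_user.setdefault(c.user_id, []).append(c.text)
    feats = [assemble_user_features(u, " ".join(text_by_user.get(u.user_id, [])),
                                    None, lexicon) for u in corpus]
    df = features_table(feats).drop(columns=["mean_chunk_score"])
    df.to_csv(cfg.path("features.csv"))
    return {"users_featurized": len(df)}


def stage_train(cfg: RunConfig) -> dict:
    chunks = _read_chunks(_require(cfg, "chunks.jsonl", "chunk"))
    split = json.loads(_require(cfg, "split.json", "chunk").read_text())
    largest = max(int(k) for k in split["train_sets"])
    train_ids = set(split["train_sets"][str(largest)])
    train_chunks = [c for c in chunks if c.user_id in train_ids]
    scorer = train_scorer(train_chunks,
                          TrainConfig(seed=stage_seed(cfg.seed, "train"),
                                      threshold=cfg.threshold))
    joblib.dump(scorer, cfg.path("scorer.joblib"))
    return {"train_chunks": len(train_chunks), "train_users": largest,
            "validation_log": scorer.validation_log}


def stage_score(cfg: RunConfig) -> dict:
    scorer = joblib.load(_require(cfg, "scorer.joblib", "train"))
    out = {}
    for name, out_name in (("chunks.jsonl", "scores.csv"),
                           ("chunks_monitoring.jsonl", "scores_monitoring.csv")):
        chunks = _read_chunks(_require(cfg, name, "chunk"))
        s = scorer.predict_score([c.text for c in chunks])
        pd.DataFrame({
            "chunk_id": [c.chunk_id for c in chunks],
            "user_id": [c.user_id for c in chunks],
            "label": [c.label for c in chunks],
            "chunk_date": [c.chunk_date.isoformat() if c.chunk_date else ""
                           for c in chunks],
            "score": s,
        }).to_csv(cfg.path(out_name), index=False)
        out[out_name] = len(chunks)
    users = pd.read_csv(cfg.path("scores.csv"))
    agg = users.groupby(["user_id", "label"], as_index=False)["score"].mean()
    agg.to_csv(cfg.path("user_scores.csv"), index=False)
    out["users_scored"] = len(agg)
    return out


def stage_fuse(cfg: RunConfig) -> dict:
    features = pd.read_csv(_require(cfg, "features.csv", "featurize"),
                           index_col="user_id")
    user_scores = pd.read_csv(_require(cfg, "user_scores.csv", "score"),
                              index_col="user_id")
    split = json.loads(_require(cfg, "split.json", "chunk").read_text())
    features["mean_chunk_score"] = user_scores["score"]
    labels = features.pop("label")
    full = complete_cases(features)
    seed = stage_seed(cfg.seed, "fuse")

    largest = max(int(k) for k in split["train_sets"])
    train_ids = [u for u in split["train_sets"][str(largest)] if u in full.index]
    test_ids = [u for u in split["test_ids"] if u in full.index]
    table = ablation_table(full.loc[train_ids], labels.loc[train_ids],
                           full.loc[test_ids], labels.loc[test_ids],
                           family=cfg.fusion_family, seed=seed)
    table.to_csv(cfg.path("ablation.tsv"), sep="\t")

    rf = fit_fusion(full.loc[train_ids], labels.loc[train_ids],
                    FusionSpec(IMPORTANCE_GROUPS, family="ensemble", seed=seed))
    imp = permutation_importance(rf, full.loc[test_ids], labels.loc[test_ids],
                                 groups=IMPORTANCE_GROUPS,
                                 repeats=cfg.importance_repeats, seed=seed)
    imp.to_csv(cfg.path("importance.tsv"), sep="\t")
    return {"complete_users": len(full),
            "retention": round(len(full) / len(features), 4),
            "fusion_rows": len(table)}


def stage_trend(cfg: RunConfig) -> dict:
    scores = pd.read_csv(_require(cfg, "scores_monitoring.csv", "score"))
    scores = scores[scores["chunk_date"] != ""]
    dates = [date.fromisoformat(d) for d in scores["chunk_date"]]
    origin = cfg.trend_origin or min(dates)
    frames = []
    for grp, sub in scores.assign(d=dates).groupby("label"):
        series = aggregate_trend(sub["d"].tolist(), sub["score"].to_numpy(),
                                 origin, end=max(dates), bin_days=cfg.bin_days,
                                 trim=cfg.trim, ma_window=cfg.ma_window,
                                 group_id=str(grp))
        frames.append(series.to_frame())
    pd.concat(frames).to_csv(cfg.path("trend.tsv"), sep="\t", index=False)
    return {"bins": len(frames[0]), "groups": len(frames)}


def stage_topics(cfg: RunConfig) -> dict:
    chunks = _read_chunks(_require(cfg, "chunks_monitoring.jsonl", "chunk"))
    model = fit_topics([c.text for c in chunks], k=cfg.k_topics,
                       seed=stage_seed(cfg.seed, "topics"))
    dates = [c.chunk_date for c in chunks]
    cut = cfg.cut_date or sorted(dates)[len(dates) // 2]
    before, after = topic_frequencies(model, chunks, cut)
    rows = []
    for summary in (before, after):
        for grp, counts in sorted(summary.counts.items()):
            for tid, n in sorted(counts.items()):
                rows.append({"period": summary.period, "group": grp,
                             "topic": tid, "n_chunks": n,
                             "keywords": " ".join(summary.keywords[tid][:5])})
    pd.DataFrame(rows).to_csv(cfg.path("topics.tsv"), sep="\t", index=False)
    return {"cut_date": cut.isoformat(), "topics": cfg.k_topics}


_STAGE_FUNCS = {
    "simulate": stage_simulate, "screen": stage_screen, "chunk": stage_chunk,
    "featurize": stage_featurize, "train": stage_train, "score": stage_score,
    "fuse": stage_fuse, "trend": stage_trend, "topics": stage_topics,
}


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in canonical order and return the run
    manifest (also written to manifest.json in the output directory)."""
    requested = set(stages) if stages else set(STAGES)
    unknown = requested - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest_path = cfg.path("manifest.json")
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else {"stages": {}})
    manifest["seed"] = cfg.seed
    before = {p.name for p in out_dir.iterdir()}
    for stage in STAGES:
        if stage not in requested:
            continue
        counts = _STAGE_FUNCS[stage](cfg)
        new = {p.name for p in out_dir.iterdir()} - before | set()
        outputs = {p.name: _sha256(p) for p in sorted(out_dir.iterdir())
                   if p.is_file() and p.name != "manifest.json"}
        manifest["stages"][stage] = {
            "seed": stage_seed(cfg.seed, stage),
            "counts": counts,
            "outputs": outputs,
        }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# --------------------------------------------------------------------------
# In-memory benchmark drivers (shared by tests and the acceptance script)
# --------------------------------------------------------------------------

def run_benchmark(seed: int, n_users: int = 800, test_n: int = 200,
                  train_size: int = 500, noise_feature: bool = True) -> dict:
    """Run the default synthetic benchmark once.

    Generates a cohort with the default planted effects, screens it, builds
    identifying-filtered 250-word chunks, trains the reference scorer on
    ``train_size`` users, and evaluates chunk-level and user-level
    classification, fusion, and permutation importance on a held-out
    ``test_n``-user test set. Optionally appends a pure-noise feature column
    for importance sanity checks.
    """
    cfg = default_config(n_users=n_users, seed=seed)
    corpus = generate_corpus(cfg)
    matcher = compile_patterns()
    screening = screen_corpus(corpus, matcher)
    by_id = {r.user_id: r for r in screening}
    identifying = {tid for r in screening for tid in r.identifying_tweet_ids}

    disclosed = [u for u in corpus if u.group == CASE and has_disclosure(u)]
    recall = float(np.mean([by_id[u.user_id].is_case for u in disclosed]))
    controls = [u for u in corpus if u.group == CONTROL]
    fpr = float(np.mean([by_id[u.user_id].is_case for u in controls]))

    split = stratified_split(corpus, test_n=test_n, train_sizes=[train_size],
                             seed=seed)
    chunks = chunk_corpus(corpus, identifying_ids=identifying)
    train_ids, test_ids = set(split.train_sets[train_size]), set(split.test_ids)
    train_chunks = [c for c in chunks if c.user_id in train_ids]
    test_chunks = [c for c in chunks if c.user_id in test_ids]
    scorer = train_scorer(train_chunks, TrainConfig(seed=seed))

    all_scores = scorer.predict_score([c.text for c in chunks])
    test_scores = np.array([s for c, s in zip(chunks, all_scores)
                            if c.user_id in test_ids])
    chunk_report = evaluate(test_scores, [c.label for c in test_chunks])
    per_user = user_scores_by_id(chunks, all_scores)
    label_by_user = {u.user_id: u.group for u in corpus}
    test_users = sorted(u for u in test_ids if u in per_user)
    user_report = evaluate([per_user[u] for u in test_users],
                           [label_by_user[u] for u in test_users], level="user")

    lexicon = CategoryLexicon.default()
    text_by_user: dict[str, list[str]] = {}
    scores_by_user: dict[str, list[float]] = {}
    for c, s in zip(chunks, all_scores):
        text_by_user.setdefault(c.user_id, []).append(c.text)
        scores_by_user.setdefault(c.user_id, []).append(float(s))
    feats = [assemble_user_features(u, " ".join(text_by_user.get(u.user_id, [])),
                                    scores_by_user.get(u.user_id), lexicon)
             for u in corpus]
    df = features_table(feats)
    labels = df.pop("label")
    if noise_feature:
        df["noise"] = np.random.default_rng([seed, 99]).normal(size=len(df))
    full = complete_cases(df)
    tr = [u for u in sorted(train_ids) if u in full.index]
    te = [u for u in sorted(test_ids) if u in full.index]

    def fuse_auc(groups):
        spec = FusionSpec(tuple(groups), family="max_margin", seed=seed)
        model = fit_fusion(full.loc[tr], labels.loc[tr], spec)
        s = predict_scores(model, full.loc[te], groups)
        return evaluate(s, labels.loc[te], level="user")

    fusion_all = fuse_auc(ALL_GROUPS)
    fusion_score_only = fuse_auc(("mean_chunk_score",))

    rf_groups = IMPORTANCE_GROUPS + (("noise",) if noise_feature else ())
    rf = fit_fusion(full.loc[tr], labels.loc[tr],
                    FusionSpec(rf_groups, family="ensemble", seed=seed))
    importance = permutation_importance(rf, full.loc[te], labels.loc[te],
                                        groups=rf_groups, repeats=10, seed=seed)

    return {
        "config": cfg, "corpus": corpus, "screening": screening,
        "split": split, "chunks": chunks, "scorer": scorer,
        "screener_recall": recall, "screener_fpr": fpr,
        "chunk_report": chunk_report, "user_report": user_report,
        "features": full, "labels": labels,
        "train_ids": tr, "test_ids": te,
        "fusion_all": fusion_all, "fusion_score_only": fusion_score_only,
        "importance": importance,
    }


TREND_CHANGEPOINT = date(2020, 3, 13)
TREND_MULTIPLIER = 2.0
MONITOR_RANGE = (date(2020, 1, 1), date(2020, 5, 22))


def _monitor_config(seed: int, n_users: int, with_trend: bool) -> SimConfig:
    # Case-only monitoring cohort (the recovery check concerns the case
    # series); dense timelines keep each 250-word chunk's time-span short
    # (~2 bins) so chunk dating does not blur the changepoint, and many
    # chunks per bin keep the bin means stable.
    cfg = default_config(
        n_users=n_users, seed=seed, case_fraction=1.0,
        tweets_per_user=(400.0, 0.05),
        date_range=MONITOR_RANGE,
        disclosure_prob_tweet=0.0, disclosure_prob_description=0.0,
    )
    if with_trend:
        cfg.trend_spec = [(TREND_CHANGEPOINT, TREND_MULTIPLIER)]
    return cfg


def run_trend_benchmark(seed: int, scorer=None, n_users: int = 500) -> dict:
    """Trend recovery: a step increase in case depression-language intensity
    at a known date, recovered from the smoothed case-group series; plus a
    no-trend null series for flatness checks (slope test on raw bin means,
    which are independent across bins under the null)."""
    if scorer is None:
        bench_cfg = default_config(n_users=400, seed=seed)
        bench = generate_corpus(bench_cfg)
        matcher = compile_patterns()
        ident = {tid for r in screen_corpus(bench, matcher)
                 for tid in r.identifying_tweet_ids}
        scorer = train_scorer(chunk_corpus(bench, identifying_ids=ident),
                              TrainConfig(seed=seed))

    out = {}
    for name, with_trend in (("trend", True), ("null", False)):
        cfg = _monitor_config(seed, n_users, with_trend)
        corpus = generate_corpus(cfg)
        chunks = chunk_corpus(corpus, mode="monitoring")
        scores = scorer.predict_score([c.text for c in chunks])
        series = trend_by_group(chunks, scores, MONITOR_RANGE[0],
                                end=MONITOR_RANGE[1])
        case_series = series[CASE]
        raw = case_series.raw()
        ok = ~np.isnan(raw)
        x = np.arange(len(raw))[ok]
        slope = stats.linregress(x, raw[ok])
        out[name] = {
            "series": series,
            "slope_p": float(slope.pvalue),
            "changepoint_estimate": estimate_changepoint(case_series),
        }
    est = out["trend"]["changepoint_estimate"]
    true_bin = (TREND_CHANGEPOINT - MONITOR_RANGE[0]).days // 3
    est_bin = (est - MONITOR_RANGE[0]).days // 3
    out["changepoint_error_bins"] = abs(est_bin - true_bin)
    return out


def run_null_calibration(seed: int, n_datasets: int = 200, n_users: int = 40,
                         category: str = "i", alpha: float = 0.05) -> dict:
    """Type-I-error calibration: with every group effect removed, how often
    does the Mann-Whitney comparison of a per-user category score reject at
    level alpha?"""
    lexicon = CategoryLexicon.default()
    rejections = 0
    from .feature_extraction import score_categories
    for i in range(n_datasets):
        cfg = null_config(n_users=n_users, seed=int(
            np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2 ** 31)))
        cfg.tweets_per_user = (15.0, 0.0)
        corpus = generate_corpus(cfg)
        vals, labels = [], []
        for u in corpus:
            text = " ".join(t.text for t in u.tweets)
            vals.append(score_categories(text, lexicon)[category])
            labels.append(u.group)
        _, p = compare_groups(vals, labels)
        rejections += p < alpha
    rate = rejections / n_datasets
    se = float(np.sqrt(alpha * (1 - alpha) / n_datasets))
    return {"rejection_rate": rate, "n_datasets": n_datasets, "alpha": alpha,
            "se": se}
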