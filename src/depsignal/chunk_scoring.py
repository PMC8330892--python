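"""Chunk-level depression scorers behind a pluggable contract.

Any backend exposing ``fit(texts, labels, config)`` and
``predict_score(texts) -> confidence in [0, 1]`` can stand behind the
pipeline - including fine-tuned transformer classifiers. The shipped
reference backend is a word n-gram (1-2) count model with a regularized
logistic head: it trains in seconds on one CPU and honours the same
training protocol (9:1 train/validation split, model selection by best
validation accuracy and F1, deterministic at a fixed seed).

User-level confidence is the arithmetic mean of a user's chunk confidences.
Evaluation reports accuracy, F1, AUC, precision and recall as percentages
at a 0.5 decision threshold.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score, roc_auc_score)

from .records import CASE
from .preprocess_chunk import SplitAssignment, TweetChunk


@dataclass
class TrainConfig:
    validation_fraction: float = 0.1  # 9:1 train/validation split
    threshold: float = 0.5
    seed: int = 0
    ngram_range: tuple[int, int] = (1, 2)
    min_df: int = 2
    C_grid: tuple[float, ...] = (0.05, 0.25, 1.0)


class ChunkScorer(ABC):
    """Contract every chunk-scoring backend implements."""

    @abstractmethod
    def fit(self, texts: list[str], labels: list[str] | np.ndarray,
            config: TrainConfig) -> "ChunkScorer": ...

    @abstractmethod
    def predict_score(self, texts: list[str]) -> np.ndarray:
        """Confidence in [0, 1] that each text comes from a case user."""


class NgramLogisticScorer(ChunkScorer):
    """Reference backend: word n-gram counts + logistic regression.

    Fitting splits the chunks 9:1 into training and validation folds,
    fits one model per regularization value and keeps the one with the best
    validation accuracy + F1 (ties -> stronger regularization), mirroring
    best-validation-checkpoint selection.
    """

    def __init__(self) -> None:
        self.vectorizer: CountVectorizer | None = None
        self.model: LogisticRegression | None = None
        self.validation_log: list[dict] = []

    def fit(self, texts, labels, config: TrainConfig | None = None) -> "NgramLogisticScorer":
        config = config or TrainConfig()
        y = np.asarray([1 if l == CASE else (1 if l == 1 else 0) for l in labels])
        if len(np.unique(y)) < 2:
            raise ValueError("training chunks must contain both classes")
        rng = np.random.default_rng(config.seed)
        n = len(texts)
        order = rng.permutation(n)
        n_val = max(1, int(round(n * config.validation_fraction)))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        if len(np.unique(y[tr_idx])) < 2:
            raise ValueError("training fold lost a class; provide more chunks")

        vec = CountVectorizer(ngram_range=config.ngram_range, min_df=config.min_df)
        X = vec.fit_transform(texts)
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]

        best = None
        self.validation_log = []
        for C in config.C_grid:
            clf = LogisticRegression(C=C, max_iter=2000, random_state=config.seed)
            clf.fit(Xtr, ytr)
            pred = clf.predict(Xval)
            acc = accuracy_score(yval, pred)
            f1 = f1_score(yval, pred, zero_division=0)
            self.validation_log.append({"C": C, "val_accuracy": acc, "val_f1": f1})
            score = acc + f1
            if best is None or score > best[0]:
                best = (score, clf)
        self.vectorizer, self.model = vec, best[1]
        return self

    def predict_score(self, texts) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("scorer is not fitted")
        return self.model.predict_proba(self.vectorizer.transform(texts))[:, 1]


def train_scorer(train_chunks: list[TweetChunk], config: TrainConfig | None = None,
                 backend: ChunkScorer | None = None) -> ChunkScorer:
    backend = backend or NgramLogisticScorer()
    texts = [c.text for c in train_chunks]
    labels = [c.label for c in train_chunks]
    return backend.fit(texts, labels, config or TrainConfig())


def user_score(chunk_scores) -> float | None:
    """Arithmetic mean of one user's chunk confidences; None if no chunks."""
    scores = list(chunk_scores)
    if not scores:
        return None
    return float(np.mean(scores))


def user_scores_by_id(chunks: list[TweetChunk], scores: np.ndarray) -> dict[str, float]:
    by_user: dict[str, list[float]] = {}
    for chunk, s in zip(chunks, scores):
        by_user.setdefault(chunk.user_id, []).append(float(s))
    return {uid: user_score(v) for uid, v in by_user.items()}


@dataclass
class MetricsReport:
    accuracy: float
    f1: float
    auc: float | None
    precision: float
    recall: float
    level: str  # "chunk" | "user"
    n: int

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "f1": self.f1, "auc": self.auc,
                "precision": self.precision, "recall": self.recall,
                "level": self.level, "n": self.n}


def evaluate(scores, labels, threshold: float = 0.5, level: str = "chunk") -> MetricsReport:
    """Standard metrics (percent) at the given threshold; AUC is the rank
    statistic and is reported missing when only one class is present."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l in (CASE, 1) else 0 for l in labels])
    pred = (s >= threshold).astype(int)
    auc = float(roc_auc_score(y, s)) * 100 if len(np.unique(y)) == 2 else None
    return MetricsReport(
        accuracy=float(accuracy_score(y, pred)) * 100,
        f1=float(f1_score(y, pred, zero_division=0)) * 100,
        auc=auc,
        precision=float(precision_score(y, pred, zero_division=0)) * 100,
        recall=float(recall_score(y, pred, zero_division=0)) * 100,
        level=level, n=len(y),
    )


@dataclass
class LearningCurvePoint:
    size: int
    chunk_report: MetricsReport
    user_report: MetricsReport


def learning_curve(chunks: list[TweetChunk], split: SplitAssignment,
                   config: TrainConfig | None = None,
                   backend_factory=NgramLogisticScorer) -> list[LearningCurvePoint]:
    """Train on each nested training set, evaluate on the fixed test set at
    chunk and user level."""
    config = config or TrainConfig()
    test_ids = set(split.test_ids)
    test_chunks = [c for c in chunks if c.user_id in test_ids]
    if not test_chunks:
        raise ValueError("no test chunks available")
    by_user_label = {c.user_id: c.label for c in chunks}

    points = []
    for size in sorted(split.train_sets):
        train_ids = set(split.train_sets[size])
        train_chunks = [c for c in chunks if c.user_id in train_ids]
        if not train_chunks:
            raise ValueError(f"training size {size} yields no chunks")
        scorer = backend_factory().fit([c.text for c in train_chunks],
                                       [c.label for c in train_chunks], config)
        s = scorer.predict_score([c.text for c in test_chunks])
        chunk_rep = evaluate(s, [c.label for c in test_chunks],
                             config.threshold, level="chunk")
        per_user = user_scores_by_id(test_chunks, s)
        uids = sorted(per_user)
        user_rep = evaluate([per_user[u] for u in uids],
                            [by_user_label[u] for u in uids],
                            config.threshold, level="user")
        points.append(LearningCurvePoint(size, chunk_rep, user_rep))
    return points
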