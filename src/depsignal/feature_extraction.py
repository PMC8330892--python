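"""Per-user feature groups for signal fusion, plus group-difference testing.

Five feature groups are computed from a user's (identifying-tweet-filtered)
timeline:

* **lexicon** - percentage of words falling in each psycholinguistic
  category, from a user-supplied category lexicon (literal words or ``stem*``
  wildcards). The shipped starter lexicon is an open stand-in for the
  proprietary dictionary used in the field.
* **sentiment** - positive and negative scores in [0, 1] from a rule-based
  valence-lexicon scorer (booster and negation rules, proportion-of-text
  style outputs).
* **engagement** - mention/reply/tweet counts and their log(x + 0.1)
  transforms (natural log).
* **personality / demographics** - pass-through covariates from a provider
  (here, the synthetic generator); personality requires at least 100
  aggregate words, mirroring the minimum input length of the external
  scoring service.
* **mean_chunk_score** - the user-level mean of chunk classifier
  confidences, merged in by the fusion stage.

Group comparisons use the two-sided Mann-Whitney U test with tie correction;
the reported U is that of the first (case) sample.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .records import AGE_BINS, CASE, TRAITS, Tweet, UserRecord

REQUIRED_CATEGORIES = ("i", "posemo", "negemo", "anx", "anger", "sad",
                       "swear", "bio", "death", "power", "work")

_MARKER = re.compile(r"^\W*<(?:allcaps|elongated|repeated)>\W*$")
_TOKEN = re.compile(r"[a-z0-9']+")


def tokenize(text: str) -> list[str]:
    """Lowercase, drop normalization markers, strip punctuation."""
    out = []
    for raw in text.lower().split():
        if _MARKER.match(raw):
            continue
        out.extend(m.group(0).replace("'", "") for m in _TOKEN.finditer(raw))
    return [t for t in out if t]


class CategoryLexicon:
    """Mapping category -> entries; an entry is a literal word or a stem
    with a trailing ``*`` wildcard."""

    def __init__(self, categories: dict[str, list[str]]):
        self.categories = {c: list(v) for c, v in categories.items()}
        self._literals: dict[str, frozenset[str]] = {}
        self._stems: dict[str, tuple[str, ...]] = {}
        for cat, entries in self.categories.items():
            lits, stems = set(), []
            for e in entries:
                if e.endswith("*"):
                    stems.append(e[:-1].lower())
                else:
                    lits.add(e.lower())
            self._literals[cat] = frozenset(lits)
            self._stems[cat] = tuple(stems)

    @classmethod
    def from_json(cls, path: str | Path) -> "CategoryLexicon":
        return cls(json.loads(Path(path).read_text()))

    @classmethod
    def default(cls) -> "CategoryLexicon":
        ref = resources.files("depsignal.data").joinpath("lexicon.json")
        return cls(json.loads(ref.read_text()))

    def matches(self, token: str, category: str) -> bool:
        if token in self._literals[category]:
            return True
        return any(token.startswith(s) for s in self._stems[category])

    def match_categories(self, token: str) -> list[str]:
        return [c for c in self.categories if self.matches(token, c)]


def score_categories(text: str, lexicon: CategoryLexicon) -> dict[str, float]:
    """Percentage of tokens matching each category; a token may count toward
    several categories. Empty text scores every category 0."""
    tokens = tokenize(text)
    scores = {c: 0.0 for c in lexicon.categories}
    if not tokens:
        return scores
    for tok in tokens:
        for c in lexicon.match_categories(tok):
            scores[c] += 1.0
    n = len(tokens)
    return {c: 100.0 * v / n for c, v in scores.items()}


# --------------------------------------------------------------------------
# Rule-based sentiment
# --------------------------------------------------------------------------

def _load_valence() -> dict:
    ref = resources.files("depsignal.data").joinpath("valence.json")
    return json.loads(ref.read_text())


_VALENCE = _load_valence()
_VALENCES: dict[str, float] = _VALENCE["valences"]
_BOOSTERS: dict[str, float] = _VALENCE["boosters"]
_NEGATORS = frozenset(_VALENCE["negators"])
_NEGATION_SCOPE = 3
_NEGATION_FACTOR = -0.74


def sentiment_scores(text: str) -> tuple[float, float]:
    """(positive, negative) scores in [0, 1].

    Each valence-lexicon hit contributes its (booster-amplified, possibly
    negation-flipped) valence; scores are the positive and absolute negative
    valence mass as a fraction of total mass plus the neutral token count.
    """
    tokens = tokenize(text)
    if not tokens:
        return 0.0, 0.0
    pos = neg = 0.0
    neutral = 0
    for i, tok in enumerate(tokens):
        v = _VALENCES.get(tok)
        if v is None:
            neutral += 1
            continue
        if i > 0 and tokens[i - 1] in _BOOSTERS:
            v += math.copysign(_BOOSTERS[tokens[i - 1]], v)
        if any(t in _NEGATORS for t in tokens[max(0, i - _NEGATION_SCOPE):i]):
            v *= _NEGATION_FACTOR
        if v > 0:
            pos += v
        else:
            neg += -v
    total = pos + neg + neutral
    if total == 0:
        return 0.0, 0.0
    return pos / total, neg / total


# --------------------------------------------------------------------------
# Engagement
# --------------------------------------------------------------------------

ENGAGEMENT_RAW = ("prop_tweets_with_mentions", "n_responses",
                  "n_unique_mentions", "n_mentions", "n_tweets")


def engagement_features(tweets: list[Tweet]) -> dict[str, float]:
    """Engagement counts plus their log(x + 0.1) transforms (natural log)."""
    n_tweets = len(tweets)
    n_responses = sum(1 for t in tweets if t.is_reply)
    all_mentions = [m for t in tweets for m in t.mentions]
    n_with = sum(1 for t in tweets if t.mentions)
    raw = {
        "prop_tweets_with_mentions": n_with / n_tweets if n_tweets else 0.0,
        "n_responses": float(n_responses),
        "n_unique_mentions": float(len(set(all_mentions))),
        "n_mentions": float(len(all_mentions)),
        "n_tweets": float(n_tweets),
    }
    raw.update({f"log_{k}": math.log(raw[k] + 0.1) for k in ENGAGEMENT_RAW})
    return raw


# --------------------------------------------------------------------------
# Group comparison
# --------------------------------------------------------------------------

def compare_groups(values, labels, case_label=CASE) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with tie correction.

    Returns (U, p) where U is the statistic of the case sample (so two
    fully separated groups with the case sample lower give U = 0).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    x = values[labels == case_label]
    y = values[labels != case_label]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# User-level assembly
# --------------------------------------------------------------------------

MIN_PERSONALITY_WORDS = 100

FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "lexicon": tuple(f"cat_{c}" for c in REQUIRED_CATEGORIES),
    "sentiment": ("sent_pos", "sent_neg"),
    "engagement": tuple(f"eng_{k}" for k in ENGAGEMENT_RAW)
    + tuple(f"eng_log_{k}" for k in ENGAGEMENT_RAW),
    "personality": tuple(f"pers_{t}" for t in TRAITS),
    "demographics": ("gender",) + tuple(
        "age_" + b.replace("<=", "le").replace(">=", "ge").replace("-", "_")
        for b in AGE_BINS),
    "mean_chunk_score": ("mean_chunk_score",),
}


@dataclass
class UserFeatures:
    user_id: str
    label: str
    category_scores: dict[str, float]
    sentiment_pos: float
    sentiment_neg: float
    engagement: dict[str, float]
    personality: dict[str, float] | None
    gender: int | None
    age_bin: str | None
    mean_chunk_score: float | None
    word_count: int = 0
    missing_groups: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        row: dict = {"user_id": self.user_id, "label": self.label}
        for c in REQUIRED_CATEGORIES:
            row[f"cat_{c}"] = self.category_scores.get(c, 0.0)
        row["sent_pos"], row["sent_neg"] = self.sentiment_pos, self.sentiment_neg
        for k in ENGAGEMENT_RAW:
            row[f"eng_{k}"] = self.engagement[k]
            row[f"eng_log_{k}"] = self.engagement[f"log_{k}"]
        for t in TRAITS:
            row[f"pers_{t}"] = self.personality.get(t) if self.personality else np.nan
        row["gender"] = self.gender if self.gender is not None else np.nan
        for b, col in zip(AGE_BINS, FEATURE_GROUPS["demographics"][1:]):
            row[col] = (float(self.age_bin == b) if self.age_bin is not None else np.nan)
        row["mean_chunk_score"] = (self.mean_chunk_score
                                   if self.mean_chunk_score is not None else np.nan)
        return row


def assemble_user_features(user: UserRecord, text: str,
                           chunk_scores: list[float] | None,
                           lexicon: CategoryLexicon,
                           covariate_provider=None) -> UserFeatures:
    """Build one user's fused feature vector.

    ``text`` is the user's concatenated (identifying-filtered) tweets - the
    category and sentiment scorers both run on the aggregate. Personality is
    declared missing below MIN_PERSONALITY_WORDS aggregate words; the mean
    chunk score is missing when no scored chunk exists.
    """
    if covariate_provider is None:
        cov = {"personality": user.personality, "gender": user.gender,
               "age_bin": user.age_bin}
    else:
        cov = covariate_provider(user.user_id) or {}
    n_words = len(tokenize(text))
    pos, neg = sentiment_scores(text)
    personality = cov.get("personality") if n_words >= MIN_PERSONALITY_WORDS else None
    mean_score = (float(np.mean(chunk_scores))
                  if chunk_scores else None)

    missing = []
    if personality is None:
        missing.append("personality")
    if cov.get("gender") is None or cov.get("age_bin") is None:
        missing.append("demographics")
    if mean_score is None:
        missing.append("mean_chunk_score")

    return UserFeatures(
        user_id=user.user_id, label=user.group,
        category_scores=score_categories(text, lexicon),
        sentiment_pos=pos, sentiment_neg=neg,
        engagement=engagement_features(user.tweets),
        personality=personality, gender=cov.get("gender"),
        age_bin=cov.get("age_bin"), mean_chunk_score=mean_score,
        word_count=n_words, missing_groups=missing,
    )


def features_table(feature_list: list[UserFeatures]) -> pd.DataFrame:
    df = pd.DataFrame([f.to_row() for f in feature_list])
    return df.set_index("user_id")


def complete_cases(df: pd.DataFrame) -> pd.DataFrame:
    """Users with every feature group present (the retention filter)."""
    return df.dropna(axis=0, how="any")
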