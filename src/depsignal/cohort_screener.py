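"""Case ascertainment by self-disclosure pattern matching.

Users who publicly state a depression diagnosis ("I was diagnosed with
depression", a "depression fighter" profile) are taken as noisy cases;
controls are sampled from users whose recent timeline and description never
mention the stem "depress". Pattern templates are data-driven (JSON) with an
optional one-word modifier slot ``{x}`` (e.g. "severe", "major", or empty),
matched case-insensitively against the raw text. Descriptions containing a
mental-health-profession term disqualify the user; matches overlapping a
non-clinical sense ("economic depression", "great depression") are voided.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import date, timedelta
from importlib import resources
from pathlib import Path

import numpy as np

from .records import UserRecord


@dataclass
class PatternSet:
    tweet_patterns: dict[str, str]
    description_patterns: dict[str, str]
    modifier_vocabulary: list[str]
    profession_exclusions: list[str]
    topic_exclusions: list[str]

    @classmethod
    def from_json(cls, path: str | Path) -> "PatternSet":
        return cls(**json.loads(Path(path).read_text()))

    @classmethod
    def default(cls) -> "PatternSet":
        ref = resources.files("depsignal.data").joinpath("patterns.json")
        return cls(**json.loads(ref.read_text()))


@dataclass
class ScreeningResult:
    user_id: str
    is_case: bool
    matched_source: str  # "tweet" | "description" | "none"
    matched_pattern_id: str | None = None
    matched_span: str = ""
    identifying_tweet_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "user_id": self.user_id,
            "is_case": self.is_case,
            "matched_source": self.matched_source,
            "matched_pattern_id": self.matched_pattern_id,
            "matched_span": self.matched_span,
            "identifying_tweet_ids": list(self.identifying_tweet_ids),
        }


class PatternCompilationError(ValueError):
    """A template failed to compile; the message names the template id."""


class Matcher:
    """Compiled disclosure patterns.

    Tweets are matched against the tweet templates; descriptions against the
    tweet templates plus the description-specific ones. The ``{x}`` slot
    accepts zero or one modifier word.
    """

    def __init__(self, pattern_set: PatternSet):
        self.pattern_set = pattern_set
        x_slot = ""
        if pattern_set.modifier_vocabulary:
            alts = "|".join(re.escape(w) for w in pattern_set.modifier_vocabulary)
            x_slot = f"(?:(?:{alts})\\s+)?"
        self.tweet_regexes = self._compile(pattern_set.tweet_patterns, x_slot)
        desc = dict(pattern_set.tweet_patterns)
        desc.update(pattern_set.description_patterns)
        self.description_regexes = self._compile(desc, x_slot)
        self._topic_exclusions = [p.lower() for p in pattern_set.topic_exclusions]

    @staticmethod
    def _compile(templates: dict[str, str], x_slot: str) -> dict[str, re.Pattern]:
        out = {}
        for pid, template in templates.items():
            try:
                out[pid] = re.compile(template.replace("{x}", x_slot), re.IGNORECASE)
            except re.error as exc:
                raise PatternCompilationError(
                    f"pattern template {pid!r} does not compile: {exc}") from exc
        return out

    def _excluded_spans(self, text: str) -> list[tuple[int, int]]:
        low = text.lower()
        spans = []
        for phrase in self._topic_exclusions:
            start = 0
            while (pos := low.find(phrase, start)) != -1:
                spans.append((pos, pos + len(phrase)))
                start = pos + 1
        return spans

    def match(self, text: str, source: str = "tweet") -> tuple[str, str] | None:
        """Return (pattern_id, matched span text) or None."""
        regexes = self.tweet_regexes if source == "tweet" else self.description_regexes
        excluded = self._excluded_spans(text)
        for pid, rx in regexes.items():
            for m in rx.finditer(text):
                if any(m.start() < e and s < m.end() for s, e in excluded):
                    continue
                return pid, m.group(0)
        return None


def compile_patterns(pattern_set: PatternSet | None = None) -> Matcher:
    return Matcher(pattern_set or PatternSet.default())


def screen_user(user: UserRecord, matcher: Matcher) -> ScreeningResult:
    """Screen one user's tweets and description.

    A user is a case iff a tweet or the description matches a disclosure
    pattern and the description contains no profession-exclusion term.
    All matching tweets are recorded for later exclusion from training text.
    """
    desc_low = user.description.lower()
    profession = any(term.lower() in desc_low
                     for term in matcher.pattern_set.profession_exclusions)

    identifying = []
    first: tuple[str, str, str] | None = None  # (source, pattern_id, span)
    for tweet in user.tweets:
        hit = matcher.match(tweet.text, source="tweet")
        if hit:
            identifying.append(tweet.tweet_id)
            if first is None:
                first = ("tweet", *hit)
    if first is None:
        hit = matcher.match(user.description, source="description")
        if hit:
            first = ("description", *hit)

    if profession or first is None:
        return ScreeningResult(user.user_id, False, "none",
                               identifying_tweet_ids=identifying)
    source, pid, span = first
    return ScreeningResult(user.user_id, True, source, pid, span, identifying)


def screen_corpus(users: list[UserRecord], matcher: Matcher) -> list[ScreeningResult]:
    return [screen_user(u, matcher) for u in users]


def select_controls(users: list[UserRecord], n: int, matcher: Matcher,
                    lookback: int = 200, seed: int = 0) -> list[str]:
    """Sample n control users from those whose description and last
    ``lookback`` tweets contain no depression-related term.

    Eligibility uses the stem "depress" anywhere (stricter than pattern
    matching) plus a full pattern check, mirroring the requirement that the
    term not appear in the recent timeline or description.
    """
    def eligible(u: UserRecord) -> bool:
        if "depress" in u.description.lower():
            return False
        if matcher.match(u.description, source="description"):
            return False
        for t in u.tweets[-lookback:]:
            if "depress" in t.text.lower() or matcher.match(t.text, source="tweet"):
                return False
        return True

    pool = [u.user_id for u in users if eligible(u)]
    if len(pool) < n:
        raise ValueError(f"eligible control pool has {len(pool)} users, need {n}")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(picked)]


def trim_timeline(user: UserRecord, anchor_date: date,
                  window_days: int = 90, max_tweets: int = 200) -> UserRecord:
    """Keep only tweets within ``window_days`` before ``anchor_date``
    (inclusive), then the most recent ``max_tweets`` of those.

    For users identified from the description, the anchor is the configured
    study end date rather than an identifying-tweet date.
    """
    lo = anchor_date - timedelta(days=window_days)
    kept = [t for t in user.tweets if lo <= t.timestamp.date() <= anchor_date]
    kept = kept[-max_tweets:]
    return UserRecord(user.user_id, user.group, user.description,
                      user.personality, user.gender, user.age_bin, kept)
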