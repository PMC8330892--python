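"""Seeded synthetic tweet corpora with the statistical structure the pipeline assumes.

The generator emulates a two-group (case/control) cohort of short-text
timelines. Tweets are bags of tokens: each token is drawn from one of the
psycholinguistic category word lists (at a group-dependent expected rate per
100 words) or from a neutral base vocabulary. A configurable fraction of
case users carries a verbatim self-disclosure phrase in a tweet or profile
description; engagement metadata (replies, mentions) and big-five /
demographic covariates are drawn from group-dependent parameters. An
optional trend specification multiplies the depression-associated category
rates of case tweets after one or more changepoint dates, for
trend-recovery experiments.

The text model is deliberately minimal: it supplies exactly the structure
the downstream stages consume (category token rates, disclosure phrases,
surface habits for the normalizer - ALL-CAPS words, elongated letters,
repeated words, punctuation runs) and nothing more.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta, timezone
from pathlib import Path

import numpy as np

from .records import AGE_BINS, CASE, CONTROL, GROUPS, TRAITS, Tweet, UserRecord


class ConfigError(ValueError):
    """A SimConfig field fails validation; the message names the field."""


# --------------------------------------------------------------------------
# Vocabulary
# --------------------------------------------------------------------------

#: Neutral filler words. None of these matches any entry of the shipped
#: category lexicon (tests enforce this), none contains the stem "depress",
#: and none carries valence in the shipped sentiment lexicon.
BASE_VOCAB = (
    "the a an and or but if then again today tomorrow yesterday morning "
    "evening night week month year time day people friend friends family "
    "house home street city town weather rain sun cloud coffee tea lunch "
    "dinner breakfast music song movie show game team ball park garden tree "
    "river mountain road car bus train plane phone screen photo picture "
    "camera book story chapter word words idea thing things place world news "
    "update post tweet thread video clip link site dog cat bird fish plant "
    "flower water air ground table chair door window kitchen bottle glass "
    "plate shirt shoes jacket bag box letter paper pen pencil class school "
    "number line circle square color blue green red yellow white black "
    "light dark soft loud quiet small big long short early late new old "
    "open closed full empty round flat warm cool cold hot north south east "
    "west left right middle corner edge top bottom side front back"
).split()

#: Concrete tokens emitted per category; every token matches at least one
#: entry of the shipped lexicon for its own category and no entry of any
#: other category.
EMISSION_VOCAB: dict[str, tuple[str, ...]] = {
    "i": ("i", "me", "my", "myself"),
    "posemo": ("happy", "love", "great", "good", "hope", "glad", "fun"),
    "negemo": ("awful", "terrible", "hate", "lonely", "worthless", "bad"),
    "anx": ("anxious", "anxiety", "worried", "nervous", "panic"),
    "anger": ("angry", "mad", "furious", "rage", "annoyed"),
    "sad": ("sad", "sadness", "unhappy", "crying", "hopeless"),
    "swear": ("damn", "hell", "crap", "shit"),
    "bio": ("sleep", "tired", "sick", "headache", "insomnia"),
    "death": ("death", "dead", "dying", "funeral"),
    "power": ("power", "boss", "control", "strong", "win"),
    "work": ("work", "job", "office", "meeting", "deadline"),
}

NEUTRAL_DESCRIPTIONS = (
    "coffee and rainy mornings",
    "amateur photographer and plant parent",
    "sports fan from the midwest",
    "cat person, occasional baker",
    "here for the memes",
    "running, reading, and road trips",
    "music first, everything else later",
    "just a small town person in a big city",
    "gardening and old movies",
    "sunsets and long walks",
)

#: The X slot of the disclosure templates ("" means no modifier).
DISCLOSURE_MODIFIERS = ("", "severe ", "major ")


def _build_disclosure_tweets() -> tuple[str, ...]:
    bank = []
    for x in DISCLOSURE_MODIFIERS:
        bank += [
            f"I have {x}depression",
            f"I developed {x}depression last year",
            f"I got {x}depression",
            f"I suffer from {x}depression",
            f"I suffered from {x}depression for years",
            f"my {x}depression has been heavy lately",
            f"I'm healing from {x}depression",
            f"I am diagnosed with {x}depression",
            f"I'm diagnosed with {x}depression",
        ]
    return tuple(bank)


DISCLOSURE_TWEETS = _build_disclosure_tweets()
DISCLOSURE_DESCRIPTIONS = (
    "depression fighter",
    "depression sufferer",
    "depression survivor",
    "depression fighter since 2015",
    "proud depression survivor",
)

MENTION_POOL = tuple(f"@user{i:03d}" for i in range(300))

TWEET_LEN_MEAN = 15.0
TWEET_LEN_RANGE = (3, 60)

# surface-habit probabilities (applied to base-vocabulary tokens only, so
# category token counts are unaffected)
P_ALLCAPS = 0.02
P_ELONGATE = 0.02
P_DUPLICATE = 0.015
P_BANG_RUN = 0.06
P_PERIOD = 0.30


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class GroupEngagement:
    """Per-group engagement behaviour.

    tweets_mean   mean timeline length (None -> SimConfig.tweets_per_user mean)
    reply_prob    P(a tweet is a reply)
    mention_prob  P(a tweet carries at least one mention)
    mention_rate  extra mentions per mention-carrying tweet (Poisson rate)
    """

    tweets_mean: float | None = None
    reply_prob: float = 0.25
    mention_prob: float = 0.35
    mention_rate: float = 0.5


@dataclass
class DemographicParams:
    female_prob: float = 0.5
    age_probs: tuple[float, float, float, float] = (0.10, 0.45, 0.27, 0.18)


#: Group-dependent expected category tokens per 100 words as
#: (control_rate, case_rate). Directions mirror the documented group
#: contrasts: cases higher on first-person, sadness, anxiety, anger, swear,
#: biological-process and death words (and somewhat higher on both affect
#: categories); controls higher on power and work words.
DEFAULT_CATEGORY_RATES: dict[str, tuple[float, float]] = {
    "i": (6.0, 9.0),
    "posemo": (3.0, 3.5),
    "negemo": (1.5, 2.5),
    "anx": (0.4, 0.6),
    "anger": (0.9, 1.1),
    "sad": (0.5, 1.0),
    "swear": (0.55, 0.8),
    "bio": (1.2, 1.8),
    "death": (0.2, 0.4),
    "power": (1.6, 1.2),
    "work": (1.6, 1.2),
}

DEFAULT_PERSONALITY_SHIFT = {
    "openness": 0.0,
    "conscientiousness": -0.12,
    "extraversion": -0.08,
    "agreeableness": -0.03,
    "neuroticism": 0.15,
}


@dataclass
class SimConfig:
    n_users: int = 800
    case_fraction: float = 0.5
    #: (mean, dispersion); timeline length ~ Poisson(gamma(1/d, mean*d)),
    #: i.e. negative binomial; dispersion 0 -> plain Poisson.
    tweets_per_user: tuple[float, float] = (45.0, 0.25)
    date_range: tuple[date, date] = (date(2020, 1, 18), date(2020, 4, 18))
    category_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_RATES))
    disclosure_prob_tweet: float = 0.6
    disclosure_prob_description: float = 0.3
    engagement_params: dict[str, GroupEngagement] = field(default_factory=lambda: {
        CONTROL: GroupEngagement(tweets_mean=None, reply_prob=0.22,
                                 mention_prob=0.35, mention_rate=0.4),
        CASE: GroupEngagement(tweets_mean=None, reply_prob=0.30,
                              mention_prob=0.28, mention_rate=0.9),
    })
    personality_shift: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PERSONALITY_SHIFT))
    demographics: dict[str, DemographicParams] = field(default_factory=lambda: {
        CONTROL: DemographicParams(female_prob=0.50, age_probs=(0.08, 0.42, 0.30, 0.20)),
        CASE: DemographicParams(female_prob=0.62, age_probs=(0.12, 0.50, 0.23, 0.15)),
    })
    trend_spec: list[tuple[date, float]] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_users <= 0:
            raise ConfigError("n_users must be positive")
        if not 0.0 <= self.case_fraction <= 1.0:
            raise ConfigError("case_fraction must lie in [0, 1]")
        mean, disp = self.tweets_per_user
        if mean <= 0 or disp < 0:
            raise ConfigError("tweets_per_user requires mean > 0 and dispersion >= 0")
        start, end = self.date_range
        if end < start:
            raise ConfigError("date_range end precedes start")
        for cat, (lo, hi) in self.category_rates.items():
            if lo < 0 or hi < 0:
                raise ConfigError(f"category_rates[{cat!r}] must be non-negative")
        for grp in GROUPS:
            total = sum(self.category_rates[c][grp == CASE] for c in self.category_rates)
            if total >= 100:
                raise ConfigError(f"category_rates for {grp} sum to >= 100 per 100 words")
        for name in ("disclosure_prob_tweet", "disclosure_prob_description"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for grp, eng in self.engagement_params.items():
            if grp not in GROUPS:
                raise ConfigError(f"engagement_params has unknown group {grp!r}")
            if not 0 <= eng.reply_prob <= 1 or not 0 <= eng.mention_prob <= 1:
                raise ConfigError(f"engagement_params[{grp!r}] probabilities must lie in [0, 1]")
            if eng.mention_rate < 0:
                raise ConfigError(f"engagement_params[{grp!r}].mention_rate must be >= 0")
        for grp, demo in self.demographics.items():
            if not 0 <= demo.female_prob <= 1:
                raise ConfigError(f"demographics[{grp!r}].female_prob must lie in [0, 1]")
            if abs(sum(demo.age_probs) - 1.0) > 1e-9 or min(demo.age_probs) < 0:
                raise ConfigError(f"demographics[{grp!r}].age_probs must be a probability vector")
        if self.trend_spec:
            for cp, mult in self.trend_spec:
                if not (start <= cp <= end):
                    raise ConfigError(f"trend_spec changepoint {cp} outside date_range")
                if mult < 0:
                    raise ConfigError("trend_spec multipliers must be non-negative")

    # -- JSON round trip (dates as ISO strings) ---------------------------
    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["date_range"] = [x.isoformat() for x in self.date_range]
        if self.trend_spec:
            d["trend_spec"] = [[cp.isoformat(), m] for cp, m in self.trend_spec]
        Path(path).write_text(json.dumps(d, indent=2, default=str))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        d = json.loads(Path(path).read_text())
        d["date_range"] = tuple(date.fromisoformat(x) for x in d["date_range"])
        d["tweets_per_user"] = tuple(d["tweets_per_user"])
        d["category_rates"] = {k: tuple(v) for k, v in d["category_rates"].items()}
        d["engagement_params"] = {k: GroupEngagement(**v) for k, v in d["engagement_params"].items()}
        d["demographics"] = {
            k: DemographicParams(female_prob=v["female_prob"], age_probs=tuple(v["age_probs"]))
            for k, v in d["demographics"].items()}
        if d.get("trend_spec"):
            d["trend_spec"] = [(date.fromisoformat(cp), m) for cp, m in d["trend_spec"]]
        return cls(**d)


def default_config(**overrides) -> SimConfig:
    """The default synthetic benchmark conditions (planted group effects)."""
    return SimConfig(**overrides)


def null_config(**overrides) -> SimConfig:
    """All group differences removed: equal category rates, engagement,
    covariates; no disclosures. Used for type-I-error calibration."""
    rates = {c: (lo, lo) for c, (lo, hi) in DEFAULT_CATEGORY_RATES.items()}
    eng = GroupEngagement(reply_prob=0.25, mention_prob=0.32, mention_rate=0.5)
    demo = DemographicParams()
    cfg = SimConfig(
        category_rates=rates,
        disclosure_prob_tweet=0.0,
        disclosure_prob_description=0.0,
        engagement_params={CONTROL: copy.deepcopy(eng), CASE: copy.deepcopy(eng)},
        personality_shift={t: 0.0 for t in TRAITS},
        demographics={CONTROL: copy.deepcopy(demo), CASE: copy.deepcopy(demo)},
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# --------------------------------------------------------------------------
# Text generation
# --------------------------------------------------------------------------

def _rates_for(config: SimConfig, group: str) -> dict[str, float]:
    idx = 1 if group == CASE else 0
    return {c: v[idx] for c, v in config.category_rates.items()}


def _draw_tweet_text(rng: np.random.Generator, rates: dict[str, float],
                     length: int | None = None) -> str:
    cats = list(rates)
    probs = np.array([rates[c] / 100.0 for c in cats])
    base_p = 1.0 - probs.sum()
    if base_p < 0:
        raise ConfigError("category rates sum to more than 100 per 100 words")
    if length is None:
        length = int(np.clip(rng.poisson(TWEET_LEN_MEAN), *TWEET_LEN_RANGE))
    draw = rng.choice(len(cats) + 1, size=length, p=np.append(probs, base_p))
    words: list[str] = []
    for k in draw:
        if k < len(cats):
            voc = EMISSION_VOCAB.get(cats[k])
            if not voc:
                raise ConfigError(f"no emission vocabulary for category {cats[k]!r}")
            words.append(voc[rng.integers(len(voc))])
        else:
            w = BASE_VOCAB[rng.integers(len(BASE_VOCAB))]
            u = rng.random()
            if u < P_ALLCAPS and len(w) >= 2:
                w = w.upper()
            elif u < P_ALLCAPS + P_ELONGATE:
                w = w + w[-1] * 3
            words.append(w)
            if rng.random() < P_DUPLICATE:
                words.append(w)
    u = rng.random()
    if u < P_BANG_RUN:
        words[-1] = words[-1] + "!" * int(rng.integers(2, 5))
    elif u < P_BANG_RUN + P_PERIOD:
        words[-1] = words[-1] + "."
    return " ".join(words)


def _draw_timestamps(rng: np.random.Generator, n: int,
                     date_range: tuple[date, date]) -> list[datetime]:
    start = datetime(*date_range[0].timetuple()[:3], tzinfo=timezone.utc)
    end = datetime(*date_range[1].timetuple()[:3], tzinfo=timezone.utc) + timedelta(days=1)
    span = (end - start).total_seconds()
    secs = np.sort(rng.uniform(0, span, size=n))
    return [start + timedelta(seconds=float(s)) for s in secs]


# --------------------------------------------------------------------------
# Corpus generation
# --------------------------------------------------------------------------

def generate_corpus(config: SimConfig) -> list[UserRecord]:
    """Generate a seeded corpus; identical config (incl. seed) gives a
    byte-identical corpus under JSON-lines serialization."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_case = int(round(config.n_users * config.case_fraction))
    mean0, disp = config.tweets_per_user

    users: list[UserRecord] = []
    for i in range(config.n_users):
        group = CASE if i < n_case else CONTROL
        eng = config.engagement_params[group]
        demo = config.demographics[group]
        rates = _rates_for(config, group)

        mean = eng.tweets_mean if eng.tweets_mean is not None else mean0
        lam = rng.gamma(1.0 / disp, mean * disp) if disp > 0 else mean
        n_tweets = max(1, int(rng.poisson(lam)))
        stamps = _draw_timestamps(rng, n_tweets, config.date_range)

        uid = f"u{i:05d}"
        tweets = []
        for j, ts in enumerate(stamps):
            text = _draw_tweet_text(rng, rates)
            is_reply = bool(rng.random() < eng.reply_prob)
            mentions: list[str] = []
            if rng.random() < eng.mention_prob:
                k = 1 + int(rng.poisson(eng.mention_rate))
                mentions = [MENTION_POOL[rng.integers(len(MENTION_POOL))]
                            for _ in range(k)]
            tweets.append(Tweet(f"{uid}_t{j:04d}", uid, ts, text, is_reply, mentions))

        description = NEUTRAL_DESCRIPTIONS[rng.integers(len(NEUTRAL_DESCRIPTIONS))]
        if group == CASE:
            if rng.random() < config.disclosure_prob_tweet:
                idx = int(rng.integers(len(tweets)))
                tweets[idx].text = DISCLOSURE_TWEETS[rng.integers(len(DISCLOSURE_TWEETS))]
            if rng.random() < config.disclosure_prob_description:
                description = DISCLOSURE_DESCRIPTIONS[rng.integers(len(DISCLOSURE_DESCRIPTIONS))]

        personality = {}
        for trait in TRAITS:
            v = rng.normal(0.5, 0.12)
            if group == CASE:
                v += config.personality_shift.get(trait, 0.0)
            personality[trait] = float(np.clip(v, 0.0, 1.0))
        gender = int(rng.random() < demo.female_prob)
        age_bin = AGE_BINS[rng.choice(4, p=np.asarray(demo.age_probs))]

        users.append(UserRecord(uid, group, description, personality,
                                gender, age_bin, tweets))

    if config.trend_spec:
        users = inject_trend(users, config.trend_spec, config)
    return users


def has_disclosure(user: UserRecord) -> bool:
    """Generator ground truth: does this user carry a verbatim disclosure
    template in a tweet or the description? (Template-bank membership;
    independent of the pattern screener.)"""
    if user.description in DISCLOSURE_DESCRIPTIONS:
        return True
    return any(t.text in DISCLOSURE_TWEETS for t in user.tweets)


def inject_trend(corpus: list[UserRecord],
                 trend_spec: list[tuple[date, float]],
                 config: SimConfig,
                 seed: int | None = None) -> list[UserRecord]:
    """Multiply the depression-associated category rates of case tweets
    after each changepoint.

    The multiplier applies to categories whose case rate exceeds the control
    rate (the "depression language"); affected tweets are redrawn from the
    boosted rates while timestamps, engagement metadata and disclosure
    tweets are left untouched. Tweets before the first changepoint, and all
    control tweets, are byte-identical to the input. A multiplier of 1
    leaves a tweet unchanged.
    """
    if not trend_spec:
        return corpus
    start, end = config.date_range
    for cp, mult in trend_spec:
        if not (start <= cp <= end):
            raise ConfigError(f"trend_spec changepoint {cp} outside date_range")
    spec = sorted(trend_spec, key=lambda x: x[0])
    boosted = [c for c, (lo, hi) in config.category_rates.items() if hi > lo]
    base = _rates_for(config, CASE)
    rng = np.random.default_rng([seed if seed is not None else config.seed, 101])

    out = copy.deepcopy(corpus)
    for user in out:
        if user.group != CASE:
            continue
        for tweet in user.tweets:
            if tweet.text in DISCLOSURE_TWEETS:
                continue
            d = tweet.timestamp.date()
            mult = None
            for cp, m in spec:
                if d >= cp:
                    mult = m
            if mult is None or mult == 1.0:
                continue
            rates = dict(base)
            for c in boosted:
                rates[c] = base[c] * mult
            tweet.text = _draw_tweet_text(rng, rates)
    return out
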