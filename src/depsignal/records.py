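"""Core record types shared by every pipeline stage.

A corpus is a list of :class:`UserRecord`; each user carries a timeline of
:class:`Tweet` objects plus the covariates (big-five personality, binary
gender, one-hot age bin) that external inference services would supply for
real accounts. Corpora serialize to JSON-lines, one user per line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator

CASE = "case"
CONTROL = "control"
GROUPS = (CASE, CONTROL)

TRAITS = ("openness", "conscientiousness", "extraversion", "agreeableness", "neuroticism")

#: Age intervals used for the one-hot age label.
AGE_BINS = ("<=18", "19-29", "30-39", ">=40")


@dataclass
class Tweet:
    tweet_id: str
    user_id: str
    timestamp: datetime
    text: str
    is_reply: bool = False
    mentions: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tweet_id": self.tweet_id,
            "timestamp": self.timestamp.astimezone(timezone.utc).isoformat(),
            "text": self.text,
            "is_reply": self.is_reply,
            "mentions": list(self.mentions),
        }

    @classmethod
    def from_dict(cls, d: dict, user_id: str) -> "Tweet":
        return cls(
            tweet_id=d["tweet_id"],
            user_id=user_id,
            timestamp=datetime.fromisoformat(d["timestamp"]),
            text=d["text"],
            is_reply=bool(d.get("is_reply", False)),
            mentions=list(d.get("mentions", [])),
        )


@dataclass
class UserRecord:
    user_id: str
    group: str  # "case" | "control"
    description: str = ""
    personality: dict[str, float] | None = None
    gender: int | None = None  # 1 = female, 0 = male (binary approximation)
    age_bin: str | None = None
    tweets: list[Tweet] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "user_id": self.user_id,
            "group": self.group,
            "description": self.description,
            "personality": self.personality,
            "gender": self.gender,
            "age_bin": self.age_bin,
            "tweets": [t.to_dict() for t in self.tweets],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UserRecord":
        return cls(
            user_id=d["user_id"],
            group=d["group"],
            description=d.get("description", ""),
            personality=d.get("personality"),
            gender=d.get("gender"),
            age_bin=d.get("age_bin"),
            tweets=[Tweet.from_dict(t, d["user_id"]) for t in d.get("tweets", [])],
        )


def write_corpus(users: Iterable[UserRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for user in users:
            fh.write(json.dumps(user.to_dict(), sort_keys=True) + "\n")


def read_corpus(path: str | Path) -> list[UserRecord]:
    users = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                users.append(UserRecord.from_dict(json.loads(line)))
    return users


def iter_timeline_dates(user: UserRecord) -> Iterator[date]:
    for t in user.tweets:
        yield t.timestamp.date()
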