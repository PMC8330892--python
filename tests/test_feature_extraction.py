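"""Lexicon scoring, rule-based sentiment, engagement, Mann-Whitney, assembly."""

import itertools
import math
from datetime import datetime, timezone

import numpy as np
import pytest

from depsignal import (CategoryLexicon, assemble_user_features, compare_groups,
                       complete_cases, engagement_features, features_table,
                       score_categories, sentiment_scores, tokenize)
from depsignal.feature_extraction import FEATURE_GROUPS, REQUIRED_CATEGORIES
from depsignal.records import CASE, Tweet, UserRecord


class TestScoreCategories:
    def test_hand_counted_example(self):
        lex = CategoryLexicon({"i": ["i"], "sad": ["sad*"]})
        scores = score_categories("i am sad", lex)
        assert scores["i"] == pytest.approx(100 / 3)
        assert scores["sad"] == pytest.approx(100 / 3)

    def test_wildcards_and_multimembership(self):
        lex = CategoryLexicon({"sad": ["sad*"], "negemo": ["sad*", "awful"]})
        scores = score_categories("sadness is awful", lex)
        assert scores["sad"] == pytest.approx(100 / 3)
        assert scores["negemo"] == pytest.approx(200 / 3)

    def test_no_match_all_zero(self, lexicon):
        scores = score_categories("table chair lamp", lexicon)
        assert all(v == 0.0 for v in scores.values())

    def test_empty_text(self, lexicon):
        assert all(v == 0.0 for v in score_categories("", lexicon).values())

    def test_planted_counts_exact(self, lexicon):
        """1000 tokens with known planted counts give exact percentages."""
        rng = np.random.default_rng(0)
        planted = {"sad": 37, "i": 120, "work": 9}
        tokens = (["sad"] * 37 + ["i"] * 120 + ["work"] * 9
                  + ["zzz"] * (1000 - 37 - 120 - 9))
        rng.shuffle(tokens)
        scores = score_categories(" ".join(tokens), lexicon)
        for cat, count in planted.items():
            assert scores[cat] == pytest.approx(count / 10)

    def test_markers_excluded_from_tokens(self):
        assert tokenize("Yes <allcaps> <elongated>, fine") == ["yes", "fine"]


class TestSentiment:
    def test_neutral_text(self):
        assert sentiment_scores("table chair lamp") == (0.0, 0.0)

    def test_empty(self):
        assert sentiment_scores("") == (0.0, 0.0)

    def test_positive_monotone_in_positive_insertions(self):
        base = "table chair lamp window door"
        prev = -1.0
        for k in range(1, 11):
            pos, _ = sentiment_scores(base + " happy" * k)
            assert pos >= prev
            prev = pos

    def test_all_positive_text(self):
        pos, neg = sentiment_scores("happy great wonderful love")
        assert pos > neg and pos > 0.5

    def test_negation_flips(self):
        pos_plain, neg_plain = sentiment_scores("i am happy")
        pos_negated, neg_negated = sentiment_scores("i am not happy")
        assert pos_plain > pos_negated
        assert neg_negated > neg_plain

    def test_bounded(self):
        for text in ("awful terrible hate", "so so happy", "not bad at all"):
            pos, neg = sentiment_scores(text)
            assert 0.0 <= pos <= 1.0 and 0.0 <= neg <= 1.0


class TestEngagement:
    def _tweets(self, flags_mentions):
        ts = datetime(2020, 1, 1, tzinfo=timezone.utc)
        return [Tweet(f"t{i}", "u", ts, "x", is_reply=r, mentions=m)
                for i, (r, m) in enumerate(flags_mentions)]

    def test_zero_replies_log_floor(self):
        eng = engagement_features(self._tweets([(False, [])] * 4))
        assert eng["log_n_responses"] == pytest.approx(math.log(0.1))

    def test_mention_proportion(self):
        tw = self._tweets([(False, ["@a"])] * 4 + [(False, [])] * 6)
        assert engagement_features(tw)["prop_tweets_with_mentions"] == pytest.approx(0.4)

    def test_mention_counts(self):
        tw = self._tweets([(False, ["@a", "@a"]), (True, ["@b"])])
        eng = engagement_features(tw)
        assert eng["n_mentions"] == 3
        assert eng["n_unique_mentions"] == 2
        assert eng["n_responses"] == 1
        assert eng["log_n_tweets"] == pytest.approx(math.log(2.1))


class TestCompareGroups:
    def test_fully_separated_groups(self):
        u, p = compare_groups([1, 2, 3, 4, 5, 6],
                              [CASE] * 3 + ["control"] * 3)
        assert u == 0.0  # case sample entirely below control
        # exact two-sided p from complete enumeration of C(6,3) splits
        assert p == pytest.approx(2 / 20)

    def test_identical_groups_p_one(self):
        _, p = compare_groups([1, 2, 3, 1, 2, 3], [CASE] * 3 + ["control"] * 3)
        assert p == pytest.approx(1.0)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2, 3], [CASE] * 3)

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=7)
        labels = np.array([CASE] * 3 + ["control"] * 4)
        u_obs, p_obs = compare_groups(values, labels)

        # oracle: U for every assignment of 3 of the 7 values to the case group
        def u_stat(x, y):
            return sum((a > b) + 0.5 * (a == b) for a in x for b in y)

        us = [u_stat(values[list(idx)],
                     np.delete(values, list(idx)))
              for idx in itertools.combinations(range(7), 3)]
        m = np.mean(us)
        p_oracle = np.mean([abs(u - m) >= abs(u_obs - m) - 1e-12 for u in us])
        assert p_obs == pytest.approx(p_oracle, abs=1e-10)


class TestAssembly:
    def _user(self, n_words, uid="u1"):
        ts = datetime(2020, 1, 1, tzinfo=timezone.utc)
        return UserRecord(uid, CASE, personality={t: 0.5 for t in
                          ("openness", "conscientiousness", "extraversion",
                           "agreeableness", "neuroticism")},
                          gender=1, age_bin="19-29",
                          tweets=[Tweet("t0", uid, ts, "x")])

    def test_personality_missing_below_word_floor(self, lexicon):
        text = " ".join(["word"] * 50)
        f = assemble_user_features(self._user(50), text, [0.5], lexicon)
        assert f.personality is None
        assert "personality" in f.missing_groups

    def test_full_vector_width(self, lexicon):
        text = " ".join(["word"] * 120)
        f = assemble_user_features(self._user(120), text, [0.2, 0.8], lexicon)
        assert f.missing_groups == []
        assert f.mean_chunk_score == pytest.approx(0.5)
        row = f.to_row()
        feature_cols = [c for c in row if c not in ("user_id", "label")]
        # 11 categories + 2 sentiment + 10 engagement + 5 personality
        # + 1 gender + 4 age + 1 mean chunk score
        assert len(feature_cols) == 34
        expected = {c for cols in FEATURE_GROUPS.values() for c in cols}
        assert set(feature_cols) == expected

    def test_completeness_filter_matches_predicate_oracle(self, lexicon):
        users = []
        for i, n_words in enumerate([50, 150, 150, 150]):
            u = self._user(n_words, uid=f"u{i}")
            text = " ".join(["word"] * n_words)
            scores = None if i == 2 else [0.4]
            users.append(assemble_user_features(u, text, scores, lexicon))
        df = features_table(users).drop(columns="label")
        kept = complete_cases(df)
        oracle = {f.user_id for f in users if not f.missing_groups}
        assert set(kept.index) == oracle == {"u1", "u3"}


def test_planted_group_differences_detected(benchmark_runs):
    """On the default benchmark, the Mann-Whitney comparison flags each
    planted category at alpha = .05 with the documented direction (cases
    higher on first-person/sad/anx/anger/swear/bio/death, lower on
    power/work)."""
    higher = ("i", "sad", "anx", "anger", "swear", "bio", "death")
    lower = ("power", "work")
    for run in benchmark_runs:
        df, labels = run["features"], run["labels"]
        y = labels.loc[df.index]
        for cat in higher + lower:
            col = df[f"cat_{cat}"]
            _, p = compare_groups(col.to_numpy(), y.to_numpy())
            assert p < 0.05, cat
            case_med = col[y == CASE].median()
            ctrl_med = col[y != CASE].median()
            assert (case_med > ctrl_med) == (cat in higher), cat
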