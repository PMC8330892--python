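"""Signal fusion over user-level feature groups, ablations, and permutation
feature importance.

The fusion step feeds selected feature groups (sentiment, demographics,
engagement, personality, lexicon, mean chunk score) into a standard
classifier - logistic regression, a max-margin SVM, or a random forest -
after z-scoring on the training fold. Feature importance is the mean drop
in a held-out score over seeded column permutations (10 repeats by default),
computed on the trained random forest.

The random forest considers every feature at each split (max_features=None)
so that its fitted predictions are invariant to duplicated feature columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .records import CASE
from .feature_extraction import FEATURE_GROUPS
from .chunk_scoring import MetricsReport, evaluate

FAMILIES = ("logistic", "max_margin", "ensemble")

#: The five non-score feature groups, in the conventional reporting order
#: (sentiment + demographics + engagement + personality + lexicon).
FIVE_GROUPS = ("sentiment", "demographics", "engagement", "personality", "lexicon")
ALL_GROUPS = FIVE_GROUPS + ("mean_chunk_score",)

#: Groups the permutation-importance random forest is trained on: the
#: textual/behavioural features without the chunk score (which would
#: otherwise dominate) and without demographics.
IMPORTANCE_GROUPS = ("sentiment", "engagement", "personality", "lexicon")


@dataclass
class FusionSpec:
    feature_groups: tuple[str, ...] = ALL_GROUPS
    family: str = "max_margin"
    seed: int = 0
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.feature_groups:
            raise ValueError("at least one feature group must be selected")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")


def group_columns(groups) -> list[str]:
    """Expand group names via FEATURE_GROUPS; anything else is taken as a
    literal feature column name (e.g. an externally supplied column)."""
    cols: list[str] = []
    for g in groups:
        cols.extend(FEATURE_GROUPS.get(g, (g,)))
    return cols


def _make_estimator(spec: FusionSpec):
    if spec.family == "logistic":
        clf = LogisticRegression(max_iter=2000, random_state=spec.seed, **spec.params)
    elif spec.family == "max_margin":
        # calibrated linear SVM, so every family exposes predict_proba
        clf = CalibratedClassifierCV(
            SVC(kernel="linear", random_state=spec.seed, **spec.params),
            ensemble=False)
    else:
        # max_features=None: duplicated columns cannot change predictions;
        # min_samples_leaf=5: full-depth trees would isolate single users on
        # noise columns and give them spurious permutation importance.
        params = dict(spec.params)
        clf = RandomForestClassifier(
            n_estimators=params.pop("n_estimators", 300),
            min_samples_leaf=params.pop("min_samples_leaf", 5),
            max_features=None, random_state=spec.seed, **params)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _binary(labels) -> np.ndarray:
    return np.asarray([1 if l in (CASE, 1) else 0 for l in labels])


def fit_fusion(features: pd.DataFrame, labels, spec: FusionSpec) -> Pipeline:
    """Fit the fusion classifier on standardized, feature-complete rows."""
    spec.validate()
    X = features[group_columns(spec.feature_groups)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("features contain missing values; apply the "
                         "completeness filter first")
    y = _binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    model = _make_estimator(spec)
    model.fit(X, y)
    return model


def predict_scores(model: Pipeline, features: pd.DataFrame,
                   groups) -> np.ndarray:
    X = features[group_columns(groups)].to_numpy(dtype=float)
    return model.predict_proba(X)[:, 1]


def ablation_table(train_features: pd.DataFrame, train_labels,
                   test_features: pd.DataFrame, test_labels,
                   group_list: list[tuple[str, ...]] | None = None,
                   family: str = "max_margin", seed: int = 0) -> pd.DataFrame:
    """One row per feature-group combination, evaluated on the held-out
    user test set. The default row set covers each single group, the
    five-group combination, the chunk score alone, and all groups."""
    if group_list is None:
        group_list = ([(g,) for g in ALL_GROUPS]
                      + [FIVE_GROUPS, ALL_GROUPS])
    rows = []
    for groups in group_list:
        spec = FusionSpec(feature_groups=tuple(groups), family=family, seed=seed)
        model = fit_fusion(train_features, train_labels, spec)
        s = predict_scores(model, test_features, groups)
        rep: MetricsReport = evaluate(s, test_labels, level="user")
        rows.append({"groups": "+".join(groups), **rep.as_dict()})
    return pd.DataFrame(rows).set_index("groups")


def permutation_importance(model: Pipeline, features: pd.DataFrame, labels,
                           groups=ALL_GROUPS, repeats: int = 10,
                           seed: int = 0, scoring: str = "accuracy") -> pd.DataFrame:
    """Per-feature importance: mean +/- sd over ``repeats`` seeded column
    permutations of (baseline score - permuted score) on the given set."""
    cols = group_columns(groups)
    X = features[cols].to_numpy(dtype=float)
    res = _sk_permutation_importance(model, X, _binary(labels),
                                     n_repeats=repeats, random_state=seed,
                                     scoring=scoring)
    return pd.DataFrame(
        {"importance_mean": res.importances_mean, "importance_sd": res.importances_std},
        index=pd.Index(cols, name="feature"),
    ).sort_values("importance_mean", ascending=False)
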