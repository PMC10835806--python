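"""Classifier benchmark over trait tables.

Eight model families (DT, GBM, kNN, LR, RF, SVM, XGBoost, LDA) are evaluated
on configurable feature groups (all traits, the guideline subset, and the
three flower parts) with a stratified 0.75:0.25 train/test split and
stratified five-fold cross-validation; accuracy and macro-F1 are reported on
both.  Permutation importance provides a uniform, model-agnostic trait
ranking for every family.

Preprocessing (one-hot encoding of nominal traits, standardisation of the
rest) is fitted inside each training fold only, so no test-set statistics
leak into training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import LabelEncoder, OneHotEncoder, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .schema import FEATURE_GROUPS, TRAIT_IDS, trait_def

__all__ = [
    "MODEL_FAMILIES",
    "make_classifier",
    "stratified_split",
    "cross_validate",
    "run_benchmark",
    "rank_importance",
    "BenchReport",
    "ImportanceRanking",
]

MODEL_FAMILIES = ("DT", "GBM", "kNN", "LR", "RF", "SVM", "XGBoost", "LDA")

#: Fixed per-family hyperparameters (no tuning loop).
FAMILY_PARAMS: dict[str, dict] = {
    "DT": {},
    "GBM": {"n_estimators": 80, "max_depth": 3},
    "kNN": {"n_neighbors": 5},
    "LR": {"max_iter": 2000},
    "RF": {"n_estimators": 200},
    "SVM": {"kernel": "rbf", "C": 10.0, "gamma": "scale"},
    # exact splits (mid-gap thresholds) matter at the few-hundred-sample
    # scale this tool works at; hist bin edges can misplace margin points
    "XGBoost": {"n_estimators": 120, "max_depth": 4, "learning_rate": 0.2,
                "verbosity": 0, "tree_method": "exact"},
    "LDA": {},
}


def _estimator(family: str, seed: int):
    p = FAMILY_PARAMS[family]
    if family == "DT":
        return DecisionTreeClassifier(random_state=seed, **p)
    if family == "GBM":
        return GradientBoostingClassifier(random_state=seed, **p)
    if family == "kNN":
        return KNeighborsClassifier(**p)
    if family == "LR":
        return LogisticRegression(random_state=seed, **p)
    if family == "RF":
        return RandomForestClassifier(random_state=seed, **p)
    if family == "SVM":
        return SVC(random_state=seed, **p)
    if family == "XGBoost":
        return XGBClassifier(random_state=seed, **p)
    if family == "LDA":
        return LinearDiscriminantAnalysis(**p)
    raise ValueError(f"unknown model family {family!r}; valid: {MODEL_FAMILIES}")


def _preprocessor(columns: list[str]) -> ColumnTransformer:
    nominal = [c for c in columns if c in TRAIT_IDS and trait_def(c).scale == "nominal"]
    numeric = [c for c in columns if c not in nominal]
    return ColumnTransformer(
        [
            ("onehot", OneHotEncoder(handle_unknown="ignore", sparse_output=False), nominal),
            ("scale", StandardScaler(), numeric),
        ],
        sparse_threshold=0.0,
    )


def make_classifier(family: str, columns: list[str], seed: int = 0) -> Pipeline:
    """Preprocessing + classifier pipeline for one model family."""
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown model family {family!r}; valid: {MODEL_FAMILIES}")
    return Pipeline([("prep", _preprocessor(columns)), ("clf", _estimator(family, seed))])


ID_COLUMNS = ("variety_id", "flower_id")


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLUMNS]


def _split_xy(table: pd.DataFrame, columns: list[str] | None = None):
    columns = columns or _feature_columns(table)
    y = table["variety_id"].to_numpy()
    return table[columns], y, columns


def stratified_split(
    table: pd.DataFrame, ratio: float = 0.75, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split of a trait table by variety.

    ``ratio`` is the training share.  Every class must have at least two
    samples; per-class proportions are preserved within one sample.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    counts = table["variety_id"].value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValueError(f"classes with a single sample cannot be split: {list(singletons.index)}")
    train, test = train_test_split(
        table, train_size=ratio, stratify=table["variety_id"], random_state=seed
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def cross_validate(
    family: str,
    table: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Stratified k-fold CV; one row per fold with accuracy and macro-F1 (%)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X, y, columns = _split_xy(table, columns)
    y = LabelEncoder().fit_transform(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        clf = make_classifier(family, columns, seed)
        clf.fit(X.iloc[tr], y[tr])
        pred = clf.predict(X.iloc[te])
        rows.append(
            {
                "fold": fold,
                "accuracy": 100.0 * accuracy_score(y[te], pred),
                "macro_f1": 100.0 * f1_score(y[te], pred, average="macro"),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class BenchReport:
    """Per (family x feature group) accuracy and macro-F1, test and CV."""

    results: pd.DataFrame

    def table(self, metric: str = "test_accuracy") -> pd.DataFrame:
        """Pivot to the families x groups grid for one metric."""
        return self.results.pivot(index="family", columns="group", values=metric)

    def winners(self) -> pd.Series:
        """Best family per group by test accuracy."""
        return self.results.loc[
            self.results.groupby("group")["test_accuracy"].idxmax()
        ].set_index("group")["family"]


def run_benchmark(
    table: pd.DataFrame,
    groups: list[str] | None = None,
    seed: int = 0,
    families: tuple[str, ...] = MODEL_FAMILIES,
    ratio: float = 0.75,
    cv_folds: int = 5,
) -> BenchReport:
    """Evaluate every model family on every feature group.

    For each (family, group) cell: fit on the stratified training split and
    score the held-out test set, and separately run stratified ``cv_folds``
    cross-validation on the whole table.  Returns a :class:`BenchReport`
    with a ``best`` flag per group.
    """
    if table["variety_id"].nunique() < 2:
        raise ValueError("benchmark needs at least two varieties")
    group_names = groups or list(FEATURE_GROUPS)
    train, test = stratified_split(table, ratio=ratio, seed=seed)
    enc = LabelEncoder().fit(table["variety_id"])
    rows = []
    for gname in group_names:
        cols = [c for c in FEATURE_GROUPS[gname] if c in table.columns]
        if not cols:
            warnings.warn(f"feature group {gname!r} has no columns in the table; skipped",
                          stacklevel=2)
            continue
        for family in families:
            clf = make_classifier(family, cols, seed)
            clf.fit(train[cols], enc.transform(train["variety_id"]))
            pred = clf.predict(test[cols])
            y_te = enc.transform(test["variety_id"])
            cv = cross_validate(family, table, k=cv_folds, seed=seed, columns=cols)
            rows.append(
                {
                    "family": family,
                    "group": gname,
                    "test_accuracy": 100.0 * accuracy_score(y_te, pred),
                    "test_macro_f1": 100.0 * f1_score(y_te, pred, average="macro"),
                    "cv_accuracy_mean": cv["accuracy"].mean(),
                    "cv_accuracy_sd": cv["accuracy"].std(ddof=1),
                    "cv_macro_f1_mean": cv["macro_f1"].mean(),
                    "cv_macro_f1_sd": cv["macro_f1"].std(ddof=1),
                }
            )
    results = pd.DataFrame(rows)
    results["best"] = False
    for gname, idx in results.groupby("group")["test_accuracy"].idxmax().items():
        results.loc[idx, "best"] = True
    return BenchReport(results)


@dataclass
class ImportanceRanking:
    """Top-k traits of one family by permutation importance."""

    family: str
    ranking: list[tuple[str, float]] = field(default_factory=list)

    def trait_ids(self) -> list[str]:
        return [t for t, _ in self.ranking]


def rank_importance(
    family: str,
    table: pd.DataFrame,
    top_k: int = 15,
    seed: int = 0,
    n_repeats: int = 10,
    columns: list[str] | None = None,
) -> ImportanceRanking:
    """Permutation-importance ranking of traits for one model family.

    The model is fitted on the stratified training split and each trait
    column is shuffled ``n_repeats`` times on the held-out test set; the
    importance of a trait is the mean accuracy drop.  Using the same
    model-agnostic measure for all eight families makes the rankings
    comparable.  Ties break toward the lower trait id.
    """
    X_cols = columns or _feature_columns(table)
    if top_k > len(X_cols):
        warnings.warn(f"top_k={top_k} clipped to {len(X_cols)} traits", stacklevel=2)
        top_k = len(X_cols)
    train, test = stratified_split(table, seed=seed)
    enc = LabelEncoder().fit(table["variety_id"])
    clf = make_classifier(family, X_cols, seed)
    clf.fit(train[X_cols], enc.transform(train["variety_id"]))
    res = permutation_importance(
        clf,
        test[X_cols],
        enc.transform(test["variety_id"]),
        scoring="accuracy",
        n_repeats=n_repeats,
        random_state=seed,
    )
    order = sorted(
        range(len(X_cols)),
        key=lambda i: (-res.importances_mean[i], int(X_cols[i][1:]) if X_cols[i].startswith("F") else i),
    )
    ranking = [(X_cols[i], float(res.importances_mean[i])) for i in order[:top_k]]
    return ImportanceRanking(family=family, ranking=ranking)
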