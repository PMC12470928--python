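"""Feature selection, SVM training and cut-off derivation for the panel.

The classification task: given a samples x features matrix of percent
methylation at panel CpGs (and merged neighbour-pair features) plus
control/case labels, find the smallest feature set that separates the
classes and express the decision rule as a cut-off on the raw methylation
scale.

Workflow mirrors the episignature-reduction study design:

* stratified 70:30 train/test split;
* training-median imputation of missing values (Sanger data are
  structurally incomplete);
* all-relevant feature selection by the shadow-feature (Boruta) scheme —
  every iteration appends a shuffled copy of each feature, fits a random
  forest, and counts how often a real feature beats the best shadow; a
  two-sided binomial test over iterations classifies features as important
  / tentative / rejected;
* exhaustive comparison of small feature combinations by cross-validated
  linear-SVM performance;
* a linear SVM on Z-transformed features (Z parameters frozen on the
  training set); for a single feature the decision boundary is solved to a
  scalar cut-off and back-transformed to a raw methylation percentage, the
  form a diagnostic lab can apply without rerunning any model.

The case class (here RTS1) is hypomethylated, so ``case_side='below'``:
samples under the cut-off are called cases.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "ClassifierModel",
    "EvalReport",
    "split_train_test",
    "impute_missing",
    "shadow_feature_select",
    "compare_combinations",
    "train_cutoff_model",
    "classify",
    "evaluate",
]

CASE_LABEL = "rts1"
CONTROL_LABEL = "control"


@dataclass
class ClassifierModel:
    """A trained linear decision rule on Z-transformed methylation.

    For a single feature the rule collapses to ``value < cutoff_raw_percent
    => case`` (when ``case_side='below'``); ``cutoff_raw_percent = z_mean +
    z_sd * cutoff_z`` exactly. Multi-feature models keep the linear weights
    and classify by the sign of the decision score.
    """

    feature_ids: list[str]
    z_mean: dict[str, float]
    z_sd: dict[str, float]
    weights: dict[str, float]
    bias: float
    case_side: str  # below | above
    cutoff_z: float | None = None
    cutoff_raw_percent: float | None = None
    seed: int = 0
    version: str = ""

    def __post_init__(self) -> None:
        if self.case_side not in {"below", "above"}:
            raise ValueError("case_side must be 'below' or 'above'")
        if self.cutoff_z is not None and self.cutoff_raw_percent is not None:
            f = self.feature_ids[0]
            expected = self.z_mean[f] + self.z_sd[f] * self.cutoff_z
            if abs(expected - self.cutoff_raw_percent) > 1e-9 * max(1.0, abs(expected)):
                raise ValueError("cutoff_raw_percent inconsistent with z parameters")

    def z_transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        z = pd.DataFrame(index=matrix.index)
        for f in self.feature_ids:
            z[f] = (matrix[f] - self.z_mean[f]) / self.z_sd[f]
        return z

    def decision_score(self, matrix: pd.DataFrame) -> pd.Series:
        """Signed score, positive on the case side of the boundary (the
        weights are oriented that way at training time)."""
        z = self.z_transform(matrix)
        return sum(self.weights[f] * z[f] for f in self.feature_ids) + self.bias

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "feature_ids": self.feature_ids,
            "z_mean": self.z_mean,
            "z_sd": self.z_sd,
            "weights": self.weights,
            "bias": self.bias,
            "case_side": self.case_side,
            "cutoff_z": self.cutoff_z,
            "cutoff_raw_percent": self.cutoff_raw_percent,
            "seed": self.seed,
            "version": self.version,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ClassifierModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        return cls(**doc)


@dataclass
class EvalReport:
    """Classification performance with confusion counts, CV and ROC."""

    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    tp: int
    fn: int
    tn: int
    fp: int
    cv_accuracy: list[float] = field(default_factory=list)
    roc_points: list[tuple[float, float]] = field(default_factory=list)  # (fpr, tpr)

    def __post_init__(self) -> None:
        total = self.tp + self.fn + self.tn + self.fp
        if total:
            expected = (self.tp + self.tn) / total
            if abs(expected - self.accuracy) > 1e-9:
                raise ValueError("accuracy inconsistent with confusion counts")

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "confusion": {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp},
            "cv_accuracy": self.cv_accuracy,
        }


# ---------------------------------------------------------------------------
# data preparation


def split_train_test(
    matrix: pd.DataFrame,
    labels: pd.Series,
    ratio: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Stratified random train/test split (train fraction = ``ratio``).

    Each class contributes ``round(n_class * ratio)`` samples to the
    training set (nearest integer, halves up), clamped so both splits keep
    at least one sample per class — e.g. 30 controls + 60 cases at 0.7
    split 21+42 train / 9+18 test. Deterministic under ``seed``.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1) — both splits must be nonempty")
    labels = labels.loc[matrix.index]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need two classes to split")
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 samples for a stratified split")
    rng = np.random.default_rng(seed)
    idx_train: list = []
    idx_test: list = []
    for cls in sorted(counts.index):
        members = labels.index[labels == cls].to_numpy()
        perm = rng.permutation(members)
        k = int(np.floor(len(members) * ratio + 0.5))
        k = min(max(k, 1), len(members) - 1)
        idx_train.extend(perm[:k])
        idx_test.extend(perm[k:])
    return (
        matrix.loc[idx_train],
        matrix.loc[idx_test],
        labels.loc[idx_train],
        labels.loc[idx_test],
    )


def impute_missing(
    train: pd.DataFrame,
    test: pd.DataFrame | None = None,
    max_missing_frac: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame | None, dict]:
    """Drop mostly-missing features; median-impute the rest.

    Features missing in more than ``max_missing_frac`` of *training*
    samples are dropped from both splits; remaining gaps are filled with
    the training-set median. The returned info dict records dropped
    features and the imputation mask.
    """
    frac = train.isna().mean()
    dropped = list(frac[frac > max_missing_frac].index)
    kept = [c for c in train.columns if c not in dropped]
    medians = train[kept].median()
    info = {
        "dropped_features": dropped,
        "train_mask": train[kept].isna(),
        "medians": medians,
    }
    train_f = train[kept].fillna(medians)
    test_f = None
    if test is not None:
        info["test_mask"] = test[kept].isna()
        test_f = test[kept].fillna(medians)
    return train_f, test_f, info


# ---------------------------------------------------------------------------
# shadow-feature (Boruta-style) selection


def shadow_feature_select(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_iter: int = 50,
    alpha: float = 0.01,
    seed: int = 0,
    n_estimators: int = 100,
    multiple_testing: bool = True,
) -> dict[str, str]:
    """All-relevant selection against shuffled shadow features.

    Each iteration appends a row-shuffled copy of every feature, fits a
    random forest, and scores a *hit* for each real feature whose impurity
    importance exceeds the best shadow importance. Over ``n_iter``
    iterations, hits are tested against Binomial(n_iter, 1/2): features
    with significantly many hits (two-sided test at ``alpha``) are
    ``important``, significantly few ``rejected``, otherwise ``tentative``.
    By default the per-feature p-values are Bonferroni-adjusted for the
    number of features, as in the standard all-relevant wrapper; pass
    ``multiple_testing=False`` for raw per-feature decisions.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two features")
    if matrix.isna().any().any():
        raise ValueError("impute missing values before feature selection")
    rng = np.random.default_rng(seed)
    X = matrix.to_numpy(dtype=float)
    y = labels.loc[matrix.index].to_numpy()
    n, f = X.shape

    hits = np.zeros(f, dtype=int)
    for _ in range(n_iter):
        shadow = X.copy()
        for j in range(f):
            shadow[:, j] = shadow[rng.permutation(n), j]
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(np.hstack([X, shadow]), y)
        imp = forest.feature_importances_
        hits += imp[:f] > imp[f:].max()

    result: dict[str, str] = {}
    for j, name in enumerate(matrix.columns):
        p = binomtest(int(hits[j]), n_iter, 0.5).pvalue
        if multiple_testing:
            p = min(1.0, p * f)
        if p < alpha:
            result[name] = "important" if hits[j] > n_iter / 2 else "rejected"
        else:
            result[name] = "tentative"
    return result


# ---------------------------------------------------------------------------
# model search and training


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    tp = int(((y_true == CASE_LABEL) & (y_pred == CASE_LABEL)).sum())
    fn = int(((y_true == CASE_LABEL) & (y_pred != CASE_LABEL)).sum())
    tn = int(((y_true != CASE_LABEL) & (y_pred != CASE_LABEL)).sum())
    fp = int(((y_true != CASE_LABEL) & (y_pred == CASE_LABEL)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(y_true)
    return sens, spec, acc


def compare_combinations(
    train: pd.DataFrame,
    labels: pd.Series,
    candidate_features: Sequence[str],
    max_k: int = 2,
    cv_folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> pd.DataFrame:
    """Cross-validated linear-SVM metrics for every feature subset of size
    <= ``max_k``, ranked by accuracy then parsimony (fewer features first).
    """
    y = labels.loc[train.index].to_numpy()
    rows = []
    for k in range(1, max_k + 1):
        for combo in itertools.combinations(candidate_features, k):
            X = train[list(combo)].to_numpy(dtype=float)
            mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Xz = (X - mu) / sd
            skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
            sens, spec, acc = [], [], []
            for tr, te in skf.split(Xz, y):
                clf = SVC(kernel="linear", C=C)
                clf.fit(Xz[tr], y[tr])
                s, p, a = _fold_metrics(y[te], clf.predict(Xz[te]))
                sens.append(s)
                spec.append(p)
                acc.append(a)
            rows.append(
                {
                    "features": "+".join(combo),
                    "n_features": k,
                    "sensitivity": float(np.nanmean(sens)),
                    "specificity": float(np.nanmean(spec)),
                    "accuracy": float(np.mean(acc)),
                }
            )
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["accuracy", "n_features", "features"], ascending=[False, True, True]
    ).reset_index(drop=True)


def train_cutoff_model(
    train: pd.DataFrame,
    labels: pd.Series,
    feature_ids: Sequence[str],
    seed: int = 0,
    C: float = 1.0,
) -> ClassifierModel:
    """Fit a linear SVM on Z-transformed training features.

    Z parameters (mean, sample sd) are frozen on the training set. With one
    feature the boundary ``w*z + b = 0`` is solved to ``cutoff_z = -b/w``
    and back-transformed to the raw percent scale. ``case_side`` comes from
    the class means (cases below the cut-off for a hypomethylation
    signature).
    """
    feature_ids = list(feature_ids)
    y = labels.loc[train.index]
    classes = set(y.unique())
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    X = train[feature_ids].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("impute missing values before training")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant feature cannot be Z-transformed")
    Xz = (X - mu) / sd

    clf = SVC(kernel="linear", C=C, random_state=seed)
    clf.fit(Xz, y.to_numpy())
    w = clf.coef_[0]
    b = float(clf.intercept_[0])
    # orient weights so a positive decision score means "case"
    case_is_positive = list(clf.classes_).index(CASE_LABEL) == 1
    if not case_is_positive:
        w, b = -w, -b

    case_mean = X[(y == CASE_LABEL).to_numpy()].mean(axis=0)
    ctrl_mean = X[(y != CASE_LABEL).to_numpy()].mean(axis=0)
    case_side = "below" if case_mean.mean() < ctrl_mean.mean() else "above"

    cutoff_z = cutoff_raw = None
    if len(feature_ids) == 1:
        cutoff_z = float(-b / w[0])
        cutoff_raw = float(mu[0] + sd[0] * cutoff_z)

    return ClassifierModel(
        feature_ids=feature_ids,
        z_mean={f: float(m) for f, m in zip(feature_ids, mu)},
        z_sd={f: float(s) for f, s in zip(feature_ids, sd)},
        weights={f: float(wi) for f, wi in zip(feature_ids, w)},
        bias=b,
        case_side=case_side,
        cutoff_z=cutoff_z,
        cutoff_raw_percent=cutoff_raw,
        seed=seed,
    )


def classify(model: ClassifierModel, matrix: pd.DataFrame) -> pd.DataFrame:
    """Apply a trained model; returns predicted label, margin and flags.

    Single-feature models use the raw-scale cut-off directly: a value on
    the case side of ``cutoff_raw_percent`` is called a case; a value
    exactly at the cut-off goes to the control side and is flagged
    borderline. Samples with a missing feature value are unclassifiable.
    """
    missing = set(model.feature_ids) - set(matrix.columns)
    if missing:
        raise KeyError(f"model features absent from matrix: {sorted(missing)}")
    out = pd.DataFrame(index=matrix.index)
    na_mask = matrix[model.feature_ids].isna().any(axis=1)

    if len(model.feature_ids) == 1 and model.cutoff_raw_percent is not None:
        values = matrix[model.feature_ids[0]]
        if model.case_side == "below":
            is_case = values < model.cutoff_raw_percent
        else:
            is_case = values > model.cutoff_raw_percent
        out["margin"] = model.decision_score(matrix)
        out["label"] = np.where(is_case, CASE_LABEL, CONTROL_LABEL)
        out["borderline"] = values == model.cutoff_raw_percent
    else:
        score = model.decision_score(matrix)
        out["margin"] = score
        out["label"] = np.where(score > 0, CASE_LABEL, CONTROL_LABEL)
        out["borderline"] = score == 0

    out.loc[na_mask, "label"] = pd.NA
    out["unclassifiable"] = na_mask
    return out


def evaluate(
    model: ClassifierModel,
    matrix: pd.DataFrame,
    labels: pd.Series,
    cv_folds: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Confusion metrics, ROC/AUC and stratified CV for a model.

    Metrics treat the case class as positive. The ROC sweeps the scalar
    decision score; AUC is the trapezoidal area. Cross-validation refits a
    fresh model with the same feature set within each stratified fold of
    the supplied data.
    """
    labels = labels.loc[matrix.index]
    binary = labels.isin([CASE_LABEL, CONTROL_LABEL])
    mat, y = matrix.loc[binary], labels.loc[binary]

    pred = classify(model, mat)
    usable = ~pred["unclassifiable"]
    y_true = y.loc[usable].to_numpy()
    y_pred = pred.loc[usable, "label"].to_numpy()
    tp = int(((y_true == CASE_LABEL) & (y_pred == CASE_LABEL)).sum())
    fn = int(((y_true == CASE_LABEL) & (y_pred != CASE_LABEL)).sum())
    tn = int(((y_true != CASE_LABEL) & (y_pred != CASE_LABEL)).sum())
    fp = int(((y_true != CASE_LABEL) & (y_pred == CASE_LABEL)).sum())

    score = pred.loc[usable, "margin"].to_numpy(dtype=float)
    fpr, tpr, _ = roc_curve(y_true == CASE_LABEL, score)
    area = float(_auc(fpr, tpr))

    cv_acc: list[float] = []
    min_class = y.loc[usable].value_counts().min()
    folds = min(cv_folds, int(min_class))
    if folds >= 2:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        X = mat.loc[usable]
        yv = y.loc[usable]
        for tr, te in skf.split(X, yv):
            m = train_cutoff_model(
                X.iloc[tr], yv.iloc[tr], model.feature_ids, seed=seed
            )
            p = classify(m, X.iloc[te])
            _, _, acc = _fold_metrics(yv.iloc[te].to_numpy(), p["label"].to_numpy())
            cv_acc.append(acc)

    total = tp + fn + tn + fp
    return EvalReport(
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        accuracy=(tp + tn) / total if total else float("nan"),
        auc=area,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        cv_accuracy=cv_acc,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
    )
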