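"""Termination-risk modelling: training, evaluation, tuning, comparison.

The modelling surface follows the Model/Results convention: a
:class:`TerminationRiskModel` is built from a design matrix (plus an
optional train/test split) and ``fit()`` returns a
:class:`TerminationRiskResults` carrying the fitted classifier, cross-
validated and held-out metrics, and a ``summary()`` table. Three
classifier families are supported — logistic regression, random forest
and extreme gradient boosting — all consuming sparse input and fully
reproducible under a fixed seed.

Evaluation is imbalance-aware throughout: fivefold stratified cross-
validation with the majority class undersampled *inside each training
fold only*, reporting ROC-AUC, balanced accuracy (mean of per-class
recalls), the F1 score with the failure class as positive, and
per-class accuracies. Two fitted models sharing a test set are compared
with McNemar's paired test on their discordant predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.stats import chi2 as chi2_dist
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, recall_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .encoding import DesignMatrix
from .selection import SplitIndices, undersample

FAMILIES = ("logistic_regression", "random_forest", "gradient_boosting")


@dataclass(slots=True, frozen=True)
class ClassifierSpec:
    """A classifier family plus its hyperparameters and seed."""

    family: str
    hyperparameters: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        hp = self.hyperparameters
        for key in ("subsample_rows", "subsample_cols"):
            if key in hp and not 0 < hp[key] <= 1:
                raise ValueError(f"{key} must be in (0, 1]")
        if "max_depth" in hp and hp["max_depth"] < 1:
            raise ValueError("max_depth must be >= 1")


def train_classifier(spec: ClassifierSpec, X_train, y_train):
    """Fit the requested family; returns a probabilistic binary classifier."""
    y = np.asarray(y_train)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")
    hp = dict(spec.hyperparameters)
    if spec.family == "logistic_regression":
        model = LogisticRegression(
            C=hp.get("C", 1.0), max_iter=int(hp.get("max_iter", 2000)),
            random_state=spec.seed,
        )
    elif spec.family == "random_forest":
        model = RandomForestClassifier(
            n_estimators=int(hp.get("n_trees", 200)),
            max_depth=int(hp["max_depth"]) if "max_depth" in hp else None,
            min_samples_leaf=int(hp.get("min_child_weight", 1)),
            max_features="sqrt",
            random_state=spec.seed,
            n_jobs=1,
        )
    else:
        model = XGBClassifier(
            n_estimators=int(hp.get("n_trees", 200)),
            max_depth=int(hp.get("max_depth", 4)),
            min_child_weight=hp.get("min_child_weight", 1.0),
            subsample=hp.get("subsample_rows", 1.0),
            colsample_bytree=hp.get("subsample_cols", 1.0),
            learning_rate=hp.get("learning_rate", 0.1),
            random_state=spec.seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
        )
    model.fit(X_train, y)
    return model


def predict_margin(model, X) -> np.ndarray:
    """Raw (log-odds) score for class 1, per classifier family."""
    if isinstance(model, XGBClassifier):
        return np.asarray(model.predict(X, output_margin=True), dtype=float)
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    p = np.clip(model.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


@dataclass(slots=True)
class EvaluationReport:
    """Imbalance-aware metric bundle; balanced accuracy is always the mean
    of the two per-class accuracies."""

    roc_auc: float
    balanced_accuracy: float
    f1_class0: float
    class0_accuracy: float
    class1_accuracy: float
    threshold: float = 0.5
    per_fold: dict[str, list[float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "roc_auc": self.roc_auc,
            "balanced_accuracy": self.balanced_accuracy,
            "f1_class0": self.f1_class0,
            "class0_accuracy": self.class0_accuracy,
            "class1_accuracy": self.class1_accuracy,
            "threshold": self.threshold,
            "per_fold": self.per_fold,
        }


def compute_metrics(y_true, p_hat, threshold: float = 0.5) -> EvaluationReport:
    """Threshold the class-1 probabilities and compute the metric bundle.

    class-k accuracy is the recall of class k; balanced accuracy their
    mean; F1 treats the failure class (0) as positive; ROC-AUC is the
    rank statistic over ``p_hat``.
    """
    y = np.asarray(y_true)
    p = np.asarray(p_hat, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC-AUC undefined: y_true contains a single class")
    pred = (p >= threshold).astype(int)
    c0 = recall_score(y, pred, pos_label=0)
    c1 = recall_score(y, pred, pos_label=1)
    return EvaluationReport(
        roc_auc=float(roc_auc_score(y, p)),
        balanced_accuracy=(c0 + c1) / 2.0,
        f1_class0=float(f1_score(y, pred, pos_label=0)),
        class0_accuracy=float(c0),
        class1_accuracy=float(c1),
        threshold=threshold,
    )


def cross_validate(
    spec: ClassifierSpec,
    X,
    y,
    n_folds: int = 5,
    seed: int = 0,
    undersample_folds: bool = True,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Stratified k-fold CV; undersampling happens inside each training fold.

    The report holds the per-fold metric values and their means.
    """
    y = np.asarray(y)
    X = sparse.csr_matrix(X) if sparse.issparse(X) else np.asarray(X)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds: dict[str, list[float]] = {
        k: [] for k in ("roc_auc", "balanced_accuracy", "f1_class0",
                        "class0_accuracy", "class1_accuracy")
    }
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
        if undersample_folds:
            keep = undersample(list(map(int, tr)), y[tr], seed=seed + 1000 * (fold + 1))
            tr = np.asarray(keep)
        model = train_classifier(replace(spec, seed=spec.seed + fold), X[tr], y[tr])
        p = model.predict_proba(X[va])[:, 1]
        rep = compute_metrics(y[va], p, threshold)
        for k in folds:
            folds[k].append(getattr(rep, k))
    return EvaluationReport(
        roc_auc=float(np.mean(folds["roc_auc"])),
        balanced_accuracy=float(np.mean(folds["balanced_accuracy"])),
        f1_class0=float(np.mean(folds["f1_class0"])),
        class0_accuracy=float(np.mean(folds["class0_accuracy"])),
        class1_accuracy=float(np.mean(folds["class1_accuracy"])),
        threshold=threshold,
        per_fold=folds,
    )


def tune_staged(
    family: str,
    X,
    y,
    grid_stage1: Mapping[str, Sequence[float]],
    grid_stage2: Mapping[str, Sequence[float]],
    seed: int = 0,
    n_folds: int = 3,
    base_hyperparameters: Mapping[str, float] | None = None,
) -> ClassifierSpec:
    """Two-stage hyperparameter search for tree models.

    Stage 1 controls model complexity (max_depth x min_child_weight);
    stage 2 fixes the stage-1 winners and adds randomness (row and column
    subsampling). Selection is by CV balanced accuracy; ties keep the
    smaller-complexity (earlier, ascending-sorted) configuration.
    """
    hp = dict(base_hyperparameters or {})

    def score(h: Mapping[str, float]) -> float:
        s = ClassifierSpec(family, dict(h), seed)
        return cross_validate(s, X, y, n_folds=n_folds, seed=seed).balanced_accuracy

    best_h, best_s = None, -np.inf
    for depth in sorted(grid_stage1.get("max_depth", [None]), key=lambda v: (v is None, v)):
        for mcw in sorted(grid_stage1.get("min_child_weight", [None]), key=lambda v: (v is None, v)):
            h = dict(hp)
            if depth is not None:
                h["max_depth"] = depth
            if mcw is not None:
                h["min_child_weight"] = mcw
            s = score(h)
            if s > best_s:
                best_h, best_s = h, s
    hp = dict(best_h)

    best_h, best_s = hp, -np.inf
    for sr in sorted(grid_stage2.get("subsample_rows", [None]), key=lambda v: (v is None, v)):
        for sc in sorted(grid_stage2.get("subsample_cols", [None]), key=lambda v: (v is None, v)):
            h = dict(hp)
            if sr is not None:
                h["subsample_rows"] = sr
            if sc is not None:
                h["subsample_cols"] = sc
            s = score(h)
            if s > best_s:
                best_h, best_s = h, s
    return ClassifierSpec(family, dict(best_h), seed)


# ---------------------------------------------------------------------------
# McNemar paired comparison

@dataclass(slots=True, frozen=True)
class ContingencyTable:
    """2x2 paired-prediction table: a both-correct, b model1-only-correct,
    c model2-only-correct, d both-wrong."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def mcnemar_table(y_true, pred_model1, pred_model2) -> ContingencyTable:
    """Tally paired correctness of two classifiers on the same test set."""
    y = np.asarray(y_true)
    p1 = np.asarray(pred_model1)
    p2 = np.asarray(pred_model2)
    if not (len(y) == len(p1) == len(p2)):
        raise ValueError("y_true and both prediction vectors must have equal length")
    ok1, ok2 = p1 == y, p2 == y
    return ContingencyTable(
        a=int(np.sum(ok1 & ok2)),
        b=int(np.sum(ok1 & ~ok2)),
        c=int(np.sum(~ok1 & ok2)),
        d=int(np.sum(~ok1 & ~ok2)),
    )


def mcnemar_test(
    table: ContingencyTable,
    continuity_correction: bool = True,
    alpha: float = 0.01,
) -> tuple[float, float, bool]:
    """McNemar's chi-squared test on the discordant counts b and c.

    With the (default) continuity correction the statistic is
    (|b - c| - 1)^2 / (b + c); without it, (b - c)^2 / (b + c). The
    p-value is the upper tail of chi-squared with 1 df; the null (equal
    performance) is rejected when p < alpha.
    """
    b, c = table.b, table.c
    if b + c == 0:
        raise ValueError("degenerate McNemar test: the models never disagree (b + c = 0)")
    if continuity_correction:
        stat = (abs(b - c) - 1) ** 2 / (b + c)
    else:
        stat = (b - c) ** 2 / (b + c)
    p = float(chi2_dist.sf(stat, df=1))
    return float(stat), p, p < alpha


# ---------------------------------------------------------------------------
# Model / Results objects

@dataclass(slots=True)
class ComparisonResult:
    table: ContingencyTable
    chi_squared: float
    p_value: float
    reject_null: bool
    alpha: float

    def as_dict(self) -> dict:
        return {
            "contingency": {"a": self.table.a, "b": self.table.b,
                            "c": self.table.c, "d": self.table.d},
            "chi_squared": self.chi_squared,
            "p_value": self.p_value,
            "reject_null": self.reject_null,
            "alpha": self.alpha,
        }


class TerminationRiskModel:
    """Early-termination risk model over an assembled design matrix.

    Parameters
    ----------
    design : DesignMatrix
        Complete (imputed, encoded) feature matrix with aligned labels.
    spec : ClassifierSpec, optional
        Classifier family and hyperparameters; defaults to gradient
        boosting with moderate depth.
    split : SplitIndices, optional
        Train/test partition over ``design.row_ids``. When given, ``fit``
        trains on the (undersampled) training rows and evaluates on the
        untouched test rows; when absent, all rows train and only CV
        metrics are reported.
    """

    def __init__(
        self,
        design: DesignMatrix,
        spec: ClassifierSpec | None = None,
        split: SplitIndices | None = None,
        undersample_ratio: float = 1.0,
        seed: int = 0,
    ):
        self.design = design
        self.spec = spec or ClassifierSpec(
            "gradient_boosting", {"max_depth": 4, "n_trees": 200}, seed
        )
        self.split = split
        self.undersample_ratio = undersample_ratio
        self.seed = seed

    @classmethod
    def from_arrays(cls, X, y, feature_names=None, row_ids=None, **kw):
        X = sparse.csr_matrix(X)
        n, d = X.shape
        design = DesignMatrix(
            row_ids=list(row_ids) if row_ids is not None else [str(i) for i in range(n)],
            column_names=list(feature_names) if feature_names is not None else [f"x{j}" for j in range(d)],
            X=X,
            y=np.asarray(y, dtype=int),
        )
        return cls(design, **kw)

    def fit(self, cv_folds: int = 5) -> "TerminationRiskResults":
        design = self.design
        labels = dict(zip(design.row_ids, design.y))
        if self.split is not None:
            train = design.subset_rows(self.split.train_ids)
            test = design.subset_rows(self.split.test_ids)
        else:
            train, test = design, None
        kept = undersample(
            train.row_ids, labels, ratio=self.undersample_ratio, seed=self.seed
        )
        balanced = train.subset_rows(kept)
        classifier = train_classifier(self.spec, balanced.X, balanced.y)
        cv_report = cross_validate(
            self.spec, train.X, train.y, n_folds=cv_folds, seed=self.seed
        )
        test_report = None
        test_probabilities = None
        if test is not None:
            test_probabilities = classifier.predict_proba(test.X)[:, 1]
            test_report = compute_metrics(test.y, test_probabilities)
        return TerminationRiskResults(
            model=self,
            classifier=classifier,
            train_ids=list(train.row_ids),
            balanced_train_ids=list(balanced.row_ids),
            cv_report=cv_report,
            test_report=test_report,
            test_probabilities=test_probabilities,
            background=balanced,
        )


@dataclass(slots=True)
class TerminationRiskResults:
    """Fit artifacts: the classifier, metric reports and attribution hooks."""

    model: TerminationRiskModel
    classifier: object
    train_ids: list[str]
    balanced_train_ids: list[str]
    cv_report: EvaluationReport
    test_report: EvaluationReport | None
    test_probabilities: np.ndarray | None
    background: DesignMatrix

    @property
    def feature_names(self) -> list[str]:
        return self.model.design.column_names

    def predict_proba(self, X) -> np.ndarray:
        return self.classifier.predict_proba(X)[:, 1]

    def test_predictions(self, threshold: float = 0.5) -> np.ndarray:
        if self.test_probabilities is None:
            raise ValueError("no test partition was supplied at construction")
        return (self.test_probabilities >= threshold).astype(int)

    def compare(
        self, other: "TerminationRiskResults", alpha: float = 0.01,
        continuity_correction: bool = True,
    ) -> ComparisonResult:
        """McNemar comparison with another fit sharing this test set."""
        if self.model.split is None or other.model.split is None:
            raise ValueError("both fits need a held-out test partition")
        if self.model.split.test_ids != other.model.split.test_ids:
            raise ValueError("the two fits must share an identical test set")
        y = self.model.design.subset_rows(self.model.split.test_ids).y
        table = mcnemar_table(y, self.test_predictions(), other.test_predictions())
        stat, p, reject = mcnemar_test(table, continuity_correction, alpha)
        return ComparisonResult(table, stat, p, reject, alpha)

    def attribute(self, x, top_k: int = 8, background_size: int = 200):
        from .interpret import attribute, background_sample

        bg = background_sample(self.background.X, background_size, self.model.seed)
        return attribute(
            self.classifier, x, bg, top_k=top_k, feature_names=self.feature_names
        )

    def flag(self, x, threshold: float = 0.5, top_k: int = 8,
             background_size: int = 200, registry_id: str = ""):
        from .interpret import background_sample, flag_protocol

        bg = background_sample(self.background.X, background_size, self.model.seed)
        return flag_protocol(
            self.classifier, x, threshold, top_k=top_k, background_sample=bg,
            feature_names=self.feature_names, registry_id=registry_id,
        )

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Termination-risk model fit",
            "=" * 58,
            f"family:            {spec.family}",
            f"hyperparameters:   {dict(spec.hyperparameters)}",
            f"seed:              {spec.seed}",
            f"training rows:     {len(self.train_ids)} "
            f"(undersampled to {len(self.balanced_train_ids)})",
            f"features:          {len(self.feature_names)}",
            "-" * 58,
            f"{'metric':<22}{'CV mean':>12}{'held-out':>14}",
        ]
        for label, attr in [
            ("ROC-AUC", "roc_auc"),
            ("balanced accuracy", "balanced_accuracy"),
            ("F1 (class 0)", "f1_class0"),
            ("class-0 accuracy", "class0_accuracy"),
            ("class-1 accuracy", "class1_accuracy"),
        ]:
            cv = getattr(self.cv_report, attr)
            held = getattr(self.test_report, attr) if self.test_report else float("nan")
            lines.append(f"{label:<22}{cv:>12.4f}{held:>14.4f}")
        lines.append("=" * 58)
        return "\n".join(lines)
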