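"""Design-matrix assembly: imputation and categorical encoding.

Numeric features are completed with a single-imputation variant of
chained-equations (MICE) imputation: missing cells start at the column
mean, then features are revisited in order of descending missingness and
each feature's originally-missing cells are overwritten with predictions
from a ridge regression on the other features, until the largest change
(on a per-column standardized scale) falls below tolerance. Fitting
happens on the training partition only; the test partition is completed
in a single pass through the stored predictors, so no information leaks
from test to train.

Categoricals are one-hot encoded with levels learned from training data;
a missing value — and any level unseen at transform time — encodes as an
all-zero block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.linear_model import Ridge


class UnimputableFeatureError(ValueError):
    """A numeric column has no observed values to learn from."""


class SchemaError(ValueError):
    """Transform-time data does not match the fitted schema."""


class AlignmentError(ValueError):
    """Feature blocks disagree on the records they cover."""


@dataclass(slots=True)
class ImputationModel:
    """Fitted chained-equation imputer: per-feature ridge predictors.

    ``coefficients[f]`` are ordered over ``feature_order`` minus f itself;
    ``init_values`` are training column means used as the starting fill.
    """

    feature_order: list[str]
    visit_order: list[str]
    coefficients: dict[str, list[float]]
    intercepts: dict[str, float]
    init_values: dict[str, float]
    clamp_bounds: dict[str, tuple[float, float]] | None
    n_iterations: int
    converged: bool
    tolerance: float
    alpha: float
    seed: int

    def to_json(self, path) -> None:
        payload = {k: getattr(self, k) for k in (
            "feature_order", "visit_order", "coefficients", "intercepts",
            "init_values", "n_iterations", "converged", "tolerance", "alpha", "seed",
        )}
        payload["clamp_bounds"] = self.clamp_bounds
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ImputationModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        if d["clamp_bounds"] is not None:
            d["clamp_bounds"] = {k: tuple(v) for k, v in d["clamp_bounds"].items()}
        return cls(**d)


def _predict_feature(
    model: ImputationModel, table: pd.DataFrame, feat: str
) -> np.ndarray:
    others = [f for f in model.feature_order if f != feat]
    x = table[others].to_numpy(dtype=float)
    pred = x @ np.asarray(model.coefficients[feat]) + model.intercepts[feat]
    if model.clamp_bounds is not None:
        lo, hi = model.clamp_bounds[feat]
        pred = np.clip(pred, lo, hi)
    return pred


def mice_fit_transform(
    numeric_table: pd.DataFrame,
    max_iter: int = 30,
    tol: float = 1e-3,
    seed: int = 0,
    alpha: float = 1e-3,
    clamp: bool = True,
) -> tuple[pd.DataFrame, ImputationModel]:
    """Fit the chained-equation imputer and return the completed table.

    Observed cells are never modified; a table with no missing values is
    returned unchanged with zero effective iterations. The procedure is
    deterministic given identical inputs.
    """
    if numeric_table.shape[1] < 2:
        raise ValueError("chained-equation imputation needs >= 2 numeric features")
    features = list(numeric_table.columns)
    table = numeric_table.astype(float).copy()
    miss_mask = table.isna()
    all_missing = [f for f in features if miss_mask[f].all()]
    if all_missing:
        raise UnimputableFeatureError(
            f"feature(s) with no observed values: {', '.join(all_missing)}"
        )

    means = {f: float(table[f].mean()) for f in features}
    stds = {f: float(s) if (s := table[f].std()) and s > 0 else 1.0 for f in features}
    bounds = (
        {f: (float(table[f].min()), float(table[f].max())) for f in features}
        if clamp
        else None
    )
    # visit features with the most missing cells first; ties by name
    visit = sorted(
        (f for f in features if miss_mask[f].any()),
        key=lambda f: (-int(miss_mask[f].sum()), f),
    )
    for f in features:
        table.loc[miss_mask[f], f] = means[f]

    model = ImputationModel(
        feature_order=features,
        visit_order=visit,
        coefficients={},
        intercepts={},
        init_values=means,
        clamp_bounds=bounds,
        n_iterations=0,
        converged=True,
        tolerance=tol,
        alpha=alpha,
        seed=seed,
    )
    if not visit:
        return table, model

    model.converged = False
    for iteration in range(1, max_iter + 1):
        max_delta = 0.0
        for f in visit:
            others = [g for g in features if g != f]
            observed = ~miss_mask[f]
            reg = Ridge(alpha=alpha)
            reg.fit(table.loc[observed, others].to_numpy(), table.loc[observed, f].to_numpy())
            model.coefficients[f] = [float(c) for c in reg.coef_]
            model.intercepts[f] = float(reg.intercept_)
            pred = _predict_feature(model, table, f)[miss_mask[f].to_numpy()]
            old = table.loc[miss_mask[f], f].to_numpy()
            if pred.size:
                max_delta = max(max_delta, float(np.max(np.abs(pred - old))) / stds[f])
            table.loc[miss_mask[f], f] = pred
        model.n_iterations = iteration
        if max_delta < tol:
            model.converged = True
            break
    return table, model


def mice_transform(numeric_table: pd.DataFrame, model: ImputationModel) -> pd.DataFrame:
    """Complete a new table with train-fitted predictors (single pass)."""
    if list(numeric_table.columns) != model.feature_order:
        raise SchemaError(
            f"feature mismatch: expected {model.feature_order}, "
            f"got {list(numeric_table.columns)}"
        )
    table = numeric_table.astype(float).copy()
    miss_mask = table.isna()
    if not miss_mask.to_numpy().any():
        return table
    for f in model.feature_order:
        table.loc[miss_mask[f], f] = model.init_values[f]
    for f in model.visit_order:
        if f in model.coefficients and miss_mask[f].any():
            table.loc[miss_mask[f], f] = _predict_feature(model, table, f)[
                miss_mask[f].to_numpy()
            ]
    return table


@dataclass(slots=True)
class EncoderSpec:
    """Per-categorical-feature level lists learned from training data."""

    levels: dict[str, list[str]]
    column_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.column_names:
            self.column_names = [
                f"{f}={lvl}" for f, lvls in self.levels.items() for lvl in lvls
            ]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"levels": self.levels, "column_names": self.column_names}, fh)

    @classmethod
    def from_json(cls, path) -> "EncoderSpec":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(levels=d["levels"], column_names=d["column_names"])


def fit_encoder(categorical_table: pd.DataFrame) -> EncoderSpec:
    """Learn sorted level lists per feature from training data (missing excluded)."""
    levels = {
        f: sorted(str(v) for v in categorical_table[f].dropna().unique())
        for f in categorical_table.columns
    }
    return EncoderSpec(levels=levels)


def one_hot(categorical_table: pd.DataFrame, spec: EncoderSpec | None = None) -> tuple[sparse.csr_matrix, EncoderSpec]:
    """One-hot encode with missing-as-zeros semantics.

    One binary column per (feature, level) seen in training; a missing
    value — or a level the encoder never saw — yields an all-zero block for
    that feature, so per-feature row sums are 0 or 1.
    """
    if spec is None:
        spec = fit_encoder(categorical_table)
    n = len(categorical_table)
    rows, cols = [], []
    offset = 0
    for f, lvls in spec.levels.items():
        if f not in categorical_table.columns:
            raise SchemaError(f"categorical feature {f!r} absent at transform time")
        index = {lvl: j for j, lvl in enumerate(lvls)}
        values = categorical_table[f]
        for i, v in enumerate(values):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            j = index.get(str(v))
            if j is not None:
                rows.append(i)
                cols.append(offset + j)
        offset += len(lvls)
    matrix = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, offset)
    )
    return matrix, spec


@dataclass(slots=True)
class DesignMatrix:
    """Final feature container: aligned rows, namespaced columns, labels."""

    row_ids: list[str]
    column_names: list[str]
    X: sparse.csr_matrix
    y: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def subset_columns(self, names: Sequence[str]) -> "DesignMatrix":
        index = {c: j for j, c in enumerate(self.column_names)}
        cols = [index[n] for n in names]
        return DesignMatrix(self.row_ids, list(names), self.X[:, cols].tocsr(), self.y)

    def subset_rows(self, ids: Sequence[str]) -> "DesignMatrix":
        index = {r: i for i, r in enumerate(self.row_ids)}
        rows = [index[r] for r in ids]
        return DesignMatrix(list(ids), self.column_names, self.X[rows].tocsr(), self.y[rows])


def assemble_design_matrix(
    blocks: Mapping[str, tuple[Sequence[str], Sequence[str], object]],
    labels: Mapping[str, int],
    row_order: Sequence[str] | None = None,
) -> DesignMatrix:
    """Concatenate feature blocks into one aligned design matrix.

    ``blocks`` maps a namespace prefix (e.g. "char", "elig", "cat",
    "term") to (row_ids, column_names, matrix). Blocks are realigned by
    registry id to a common row order; a block missing any required id is
    an alignment error. Column names are prefixed with their namespace.
    """
    if not blocks:
        raise ValueError("no feature blocks given")
    if row_order is None:
        first = next(iter(blocks.values()))
        row_order = list(first[0])
    missing_labels = [r for r in row_order if r not in labels]
    if missing_labels:
        raise AlignmentError(f"rows without labels: {missing_labels[:5]}")

    mats, names = [], []
    for prefix, (row_ids, col_names, matrix) in blocks.items():
        index = {r: i for i, r in enumerate(row_ids)}
        absent = [r for r in row_order if r not in index]
        if absent:
            raise AlignmentError(
                f"block {prefix!r} missing record(s): {absent[:5]}"
            )
        order = [index[r] for r in row_order]
        m = sparse.csr_matrix(matrix, dtype=float)[order]
        if m.shape[1] != len(col_names):
            raise AlignmentError(f"block {prefix!r}: column-name/width mismatch")
        mats.append(m)
        names.extend(f"{prefix}:{c}" for c in col_names)
    if len(set(names)) != len(names):
        raise AlignmentError("duplicate column names after namespacing")
    X = sparse.hstack(mats, format="csr")
    y = np.array([labels[r] for r in row_order], dtype=int)
    return DesignMatrix(list(row_order), names, X, y)
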