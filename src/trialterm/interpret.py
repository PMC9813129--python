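"""Local additive attribution of individual predictions.

Per-prediction Shapley values for the fitted tree ensemble, computed in
margin (log-odds) space under the interventional convention: the value
of a feature coalition S is the mean model margin with the features in S
taken from the instance and the rest replaced by a background row, then
averaged over a seeded background sample of the training data. For tree
ensembles the values are computed *exactly* by a path recursion — at
each split where the instance and the background row part ways, both
coalition assignments are followed and every reached leaf contributes a
closed-form Shapley weight. By linearity, averaging per-background-row
values equals attributing against the background mean game, so the
result coincides with full 2^d coalition enumeration (available here as
:func:`exact_shapley_oracle` for small d).

Attribution feeds protocol flagging: when the predicted success
probability of a study falls below a threshold, the top contributors
(failure-direction first) are reported for clinical review.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import factorial
from typing import Callable, Sequence

import numpy as np


@dataclass(slots=True)
class Tree:
    """One regression tree in arrays; feature < 0 marks a leaf.

    Routing: x goes left iff x[feature] < threshold.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray

    def predict_one(self, x: np.ndarray) -> float:
        node = 0
        while self.feature[node] >= 0:
            node = (
                self.left[node]
                if x[self.feature[node]] < self.threshold[node]
                else self.right[node]
            )
        return float(self.value[node])


@dataclass(slots=True)
class ShapleyTreeModel:
    """A bare tree ensemble with an additive intercept, margin-space."""

    trees: list[Tree]
    intercept: float = 0.0
    n_features: int = 0

    def predict_margin(self, X: np.ndarray) -> np.ndarray:
        # route in float32 precision, matching xgboost's internal comparisons
        X = np.atleast_2d(np.asarray(X, dtype=np.float32)).astype(float)
        out = np.full(X.shape[0], self.intercept)
        for t in self.trees:
            out += np.array([t.predict_one(row) for row in X])
        return out


def tree_from_arrays(feature, threshold, left, right, value) -> Tree:
    return Tree(
        np.asarray(feature, dtype=int),
        np.asarray(threshold, dtype=float),
        np.asarray(left, dtype=int),
        np.asarray(right, dtype=int),
        np.asarray(value, dtype=float),
    )


def _trees_from_xgboost(booster, n_features: int) -> list[Tree]:
    """Parse an xgboost booster dump into Tree arrays."""
    names = booster.feature_names
    name_index = {n: i for i, n in enumerate(names)} if names else None
    trees = []
    for dump in booster.get_dump(dump_format="json"):
        nodes = {}

        def collect(d):
            nodes[d["nodeid"]] = d
            for child in d.get("children", ()):
                collect(child)

        collect(json.loads(dump))
        size = max(nodes) + 1
        feature = np.full(size, -1, dtype=int)
        threshold = np.zeros(size)
        left = np.zeros(size, dtype=int)
        right = np.zeros(size, dtype=int)
        value = np.zeros(size)
        for nid, d in nodes.items():
            if "leaf" in d:
                value[nid] = d["leaf"]
            else:
                split = d["split"]
                if name_index is not None and split in name_index:
                    feature[nid] = name_index[split]
                else:
                    feature[nid] = int(str(split).lstrip("f"))
                # dump prints the shortest decimal for the float32 threshold;
                # cast back so boundary comparisons match xgboost exactly
                threshold[nid] = float(np.float32(d["split_condition"]))
                left[nid] = d["yes"]
                right[nid] = d["no"]
        trees.append(Tree(feature, threshold, left, right, value))
    return trees


def _as_tree_model(model, n_features: int) -> ShapleyTreeModel:
    if isinstance(model, ShapleyTreeModel):
        return model
    booster = model.get_booster() if hasattr(model, "get_booster") else model
    trees = _trees_from_xgboost(booster, n_features)
    # recover the additive intercept empirically from one margin evaluation
    probe = np.zeros((1, n_features))
    raw = float(margin_function(model)(probe)[0])
    total = sum(t.predict_one(probe[0]) for t in trees)
    return ShapleyTreeModel(trees=trees, intercept=raw - total, n_features=n_features)


def margin_function(model) -> Callable[[np.ndarray], np.ndarray]:
    """Margin-space prediction callable for any supported model."""
    if isinstance(model, ShapleyTreeModel):
        return model.predict_margin
    if hasattr(model, "predict_proba"):  # XGBClassifier
        return lambda X: np.asarray(
            model.predict(np.atleast_2d(np.asarray(X, dtype=float)), output_margin=True),
            dtype=float,
        ).ravel()
    if hasattr(model, "inplace_predict"):  # raw xgboost Booster
        return lambda X: np.asarray(
            model.inplace_predict(
                np.atleast_2d(np.asarray(X, dtype=float)), predict_type="margin"
            ),
            dtype=float,
        ).ravel()
    raise TypeError(f"unsupported model type {type(model)!r}")


def _tree_shapley(tree: Tree, x: np.ndarray, z: np.ndarray, phi: np.ndarray) -> None:
    """Accumulate exact interventional Shapley values of one tree for the
    pair (instance x, background row z) into ``phi``."""
    active: dict[int, bool] = {}  # feature -> True if taken from x

    def rec(node: int) -> None:
        f = tree.feature[node]
        if f < 0:
            u = len(active)
            if u == 0:
                return
            v = tree.value[node]
            a = sum(active.values())
            fu = factorial(u)
            w_in = factorial(a - 1) * factorial(u - a) / fu if a > 0 else 0.0
            w_out = factorial(a) * factorial(u - a - 1) / fu if a < u else 0.0
            for k, from_x in active.items():
                phi[k] += v * w_in if from_x else -v * w_out
            return
        t = tree.threshold[node]
        x_child = tree.left[node] if x[f] < t else tree.right[node]
        z_child = tree.left[node] if z[f] < t else tree.right[node]
        if f in active:
            rec(x_child if active[f] else z_child)
        elif x_child == z_child:
            rec(x_child)
        else:
            active[f] = True
            rec(x_child)
            active[f] = False
            rec(z_child)
            del active[f]

    rec(0)


def tree_shapley_values(
    model: ShapleyTreeModel, x: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, float]:
    """Exact interventional Shapley values and the base value.

    Returns (phi, base) with base the mean margin over the background and
    base + phi.sum() equal to the model margin at x (local accuracy).
    """
    x = np.asarray(x, dtype=np.float32).astype(float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=np.float32)).astype(float)
    phi = np.zeros(len(x))
    for z in background:
        for tree in model.trees:
            _tree_shapley(tree, x, z, phi)
    phi /= len(background)
    base = float(np.mean(model.predict_margin(background)))
    return phi, base


@dataclass(slots=True)
class AttributionReport:
    """Additive explanation of one prediction in margin space.

    ``base_value`` is the average model margin over the training
    background; ``output_value`` = base + sum of contributions and equals
    the model margin at the instance. Positive contributions push toward
    success (class 1), negative toward failure (class 0).
    """

    registry_id: str
    base_value: float
    output_value: float
    contributions: dict[str, float]
    top_contributors: list[tuple[str, float, str]]

    def as_dict(self) -> dict:
        return {
            "registry_id": self.registry_id,
            "base_value": self.base_value,
            "output_value": self.output_value,
            "contributions": self.contributions,
            "top_contributors": [
                {"feature": f, "contribution": v, "direction": s}
                for f, v, s in self.top_contributors
            ],
        }


def background_sample(X, size: int = 200, seed: int = 0) -> np.ndarray:
    """Seeded dense subsample of training rows used as the background."""
    from scipy import sparse

    n = X.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=min(size, n), replace=False)
    rows = X[idx]
    return np.asarray(rows.todense() if sparse.issparse(rows) else rows, dtype=float)


def attribute(
    model,
    x,
    background_sample: np.ndarray,
    top_k: int = 8,
    feature_names: Sequence[str] | None = None,
    registry_id: str = "",
) -> AttributionReport:
    """Shapley attribution of one prediction against a training background.

    Works on any supported tree ensemble (xgboost classifier/booster or a
    bare :class:`ShapleyTreeModel`); contributions are exact, not
    sampled, and satisfy local accuracy to numerical precision.
    """
    bg = np.atleast_2d(np.asarray(background_sample, dtype=float))
    if bg.shape[0] == 0:
        raise ValueError("background sample is empty")
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != bg.shape[1]:
        raise ValueError(
            f"schema mismatch: instance has {x.shape[0]} features, "
            f"background has {bg.shape[1]}"
        )
    tm = _as_tree_model(model, len(x))
    phi, base = tree_shapley_values(tm, x, bg)
    names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(len(x))]
    if len(names) != len(x):
        raise ValueError("feature_names length does not match the instance")
    order = sorted(range(len(x)), key=lambda j: (-abs(phi[j]), names[j]))
    top = [
        (names[j], float(phi[j]), "success" if phi[j] >= 0 else "failure")
        for j in order[:top_k]
        if phi[j] != 0.0
    ]
    return AttributionReport(
        registry_id=registry_id,
        base_value=base,
        output_value=base + float(phi.sum()),
        contributions={names[j]: float(phi[j]) for j in range(len(x))},
        top_contributors=top,
    )


def exact_shapley_oracle(model, x, background_sample: np.ndarray) -> np.ndarray:
    """Exact Shapley values by full 2^d coalition enumeration.

    The value of a coalition S is the mean margin with out-of-coalition
    features replaced by background values. Refuses more than 12 features
    (combinatorial guard); intended for verification at small d.
    """
    x = np.asarray(x, dtype=float).ravel()
    d = len(x)
    if d > 12:
        raise ValueError(f"exact enumeration refused for d={d} > 12 features")
    bg = np.atleast_2d(np.asarray(background_sample, dtype=float))
    f = margin_function(model)

    def value(coalition: tuple[int, ...]) -> float:
        rows = bg.copy()
        rows[:, list(coalition)] = x[list(coalition)]
        return float(np.mean(f(rows)))

    cache = {
        subset: value(subset)
        for r in range(d + 1)
        for subset in combinations(range(d), r)
    }
    phi = np.zeros(d)
    for i in range(d):
        others = [j for j in range(d) if j != i]
        for r in range(d):
            w = factorial(r) * factorial(d - r - 1) / factorial(d)
            for subset in combinations(others, r):
                with_i = tuple(sorted(subset + (i,)))
                phi[i] += w * (cache[with_i] - cache[subset])
    return phi


@dataclass(slots=True)
class FlagReport:
    """Outcome of threshold-triggered protocol review for one study."""

    registry_id: str
    predicted_success_probability: float
    threshold: float
    flagged: bool
    flagged_features: list[tuple[str, float, str]] = field(default_factory=list)
    attribution: AttributionReport | None = None
    narrative: str = ""

    def as_dict(self) -> dict:
        return {
            "registry_id": self.registry_id,
            "predicted_success_probability": self.predicted_success_probability,
            "threshold": self.threshold,
            "flagged": self.flagged,
            "flagged_features": [
                {"feature": f, "contribution": v, "direction": s}
                for f, v, s in self.flagged_features
            ],
            "attribution": self.attribution.as_dict() if self.attribution else None,
            "narrative": self.narrative,
        }


def _success_probability(model, x: np.ndarray) -> float:
    if hasattr(model, "predict_proba"):
        return float(model.predict_proba(np.atleast_2d(x))[0, 1])
    margin = float(margin_function(model)(np.atleast_2d(x))[0])
    return float(1.0 / (1.0 + np.exp(-margin)))


def flag_protocol(
    model,
    x,
    threshold: float,
    top_k: int = 8,
    background_sample: np.ndarray | None = None,
    feature_names: Sequence[str] | None = None,
    registry_id: str = "",
) -> FlagReport:
    """Flag a study protocol whose predicted success probability is low.

    When the probability falls below ``threshold`` the attribution report
    is attached and the top contributors are listed, failure-direction
    features first, so clinicians can reconsider the flagged protocol
    elements. Otherwise only the probability is reported.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    x = np.asarray(x, dtype=float).ravel()
    p = _success_probability(model, x)
    if p >= threshold:
        return FlagReport(registry_id, p, threshold, flagged=False,
                          narrative=f"predicted success probability {p:.3f} "
                                    f">= threshold {threshold}; no review triggered")
    if background_sample is None:
        raise ValueError("flagging requires a background sample for attribution")
    report = attribute(model, x, background_sample, top_k=top_k,
                       feature_names=feature_names, registry_id=registry_id)
    failure_first = sorted(report.top_contributors, key=lambda t: t[1] >= 0)
    lines = [
        f"study {registry_id or '<unnamed>'}: predicted success probability "
        f"{p:.3f} < threshold {threshold} — protocol flagged for review.",
        "top contributors (failure-direction first):",
    ]
    lines += [f"  {f:<40} {v:+.4f} ({s})" for f, v, s in failure_first]
    return FlagReport(
        registry_id=registry_id,
        predicted_success_probability=p,
        threshold=threshold,
        flagged=True,
        flagged_features=failure_first,
        attribution=report,
        narrative="\n".join(lines),
    )
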