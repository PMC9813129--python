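"""Splitting, class rebalancing and feature selection.

The pipeline order matters and is fixed: split train/test first, then
randomly undersample the majority (success) class *of the training
partition only* to a 1:1 ratio, then score features on the undersampled
training data with the one-way ANOVA F statistic and keep the k best.
The test partition keeps its natural ~15:85 failure:success imbalance.
The feature-count k is chosen from an ablation curve (error vs number of
features) via the knee of the curve: the grid point with maximum
perpendicular distance from the chord joining the curve's endpoints
after min-max normalizing both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.feature_selection import f_classif
from sklearn.model_selection import train_test_split


class StratificationError(ValueError):
    pass


@dataclass(slots=True)
class SplitIndices:
    train_ids: list[str]
    test_ids: list[str]
    ratio: float
    seed: int
    stratified: bool


def split_train_test(
    ids: Sequence[str],
    labels: Sequence[int],
    ratio: float = 0.70,
    seed: int = 0,
    stratified: bool = True,
) -> SplitIndices:
    """Deterministic train/test partition (default 70:30, stratified)."""
    y = np.asarray(labels)
    if stratified and len(np.unique(y)) < 2:
        raise StratificationError("stratified split needs both classes present")
    train_ids, test_ids = train_test_split(
        list(ids),
        train_size=ratio,
        random_state=seed,
        stratify=y if stratified else None,
        shuffle=True,
    )
    return SplitIndices(list(train_ids), list(test_ids), ratio, seed, stratified)


def undersample(
    train_ids: Sequence[str],
    labels: dict[str, int] | Sequence[int],
    ratio: float = 1.0,
    seed: int = 0,
) -> list[str]:
    """Randomly drop majority-class training rows to minority:majority = ratio.

    Every minority sample is kept; with the default ratio 1.0 the classes
    come out exactly equal. Only the ids passed in are touched — the test
    partition never enters this function.
    """
    if ratio <= 0:
        raise ValueError("undersampling ratio must be positive")
    if isinstance(labels, dict):
        y = np.array([labels[i] for i in train_ids])
    else:
        y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("undersampling needs both classes in the training set")
    order = np.argsort(counts, kind="stable")
    minority, majority = classes[order[0]], classes[order[1]]
    n_min = counts.min()
    n_keep = min(int(round(n_min / ratio)), counts.max())
    rng = np.random.default_rng(seed)
    maj_positions = np.flatnonzero(y == majority)
    keep_maj = set(rng.choice(maj_positions, size=n_keep, replace=False))
    return [
        i for pos, i in enumerate(train_ids) if y[pos] == minority or pos in keep_maj
    ]


@dataclass(slots=True)
class FeatureRanking:
    """ANOVA-F scores with a deterministic rank order.

    ``scores`` holds NaN for features where F is undefined (zero overall
    variance); those rank last. Ties break by ascending feature name.
    """

    feature_names: list[str]
    scores: np.ndarray
    order: list[int] = field(default_factory=list)
    k_selected: int | None = None

    def __post_init__(self):
        if not self.order:
            keyed = sorted(
                range(len(self.feature_names)),
                key=lambda j: (
                    np.isnan(self.scores[j]),
                    -(self.scores[j] if not np.isnan(self.scores[j]) else 0.0),
                    self.feature_names[j],
                ),
            )
            self.order = keyed

    @property
    def n_defined(self) -> int:
        return int(np.sum(~np.isnan(self.scores)))


def anova_f_scores(X, y, feature_names: Sequence[str] | None = None) -> FeatureRanking:
    """Per-feature one-way two-group ANOVA F statistic.

    For a binary target this equals the squared equal-variance two-sample
    t statistic. Zero-variance columns get an undefined (NaN) score and
    rank last.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("ANOVA-F scoring needs both classes present")
    from scipy import sparse as sp

    n_features = X.shape[1]
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(n_features)]
    if sp.issparse(X):
        dense_var = np.asarray(X.power(2).mean(axis=0)).ravel() - np.asarray(
            X.mean(axis=0)
        ).ravel() ** 2
    else:
        dense_var = np.var(np.asarray(X, dtype=float), axis=0)
    constant = dense_var <= 0
    scores = np.full(n_features, np.nan)
    if (~constant).any():
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_vals, _ = f_classif(X, y)
        scores[~constant] = f_vals[~constant]
    return FeatureRanking(list(feature_names), scores)


def select_k_best(ranking: FeatureRanking, k: int) -> list[str]:
    """The k features with highest F, ties broken by ascending name."""
    if not 1 <= k <= ranking.n_defined:
        raise ValueError(
            f"k must be in [1, {ranking.n_defined}] (defined-score features); got {k}"
        )
    return [ranking.feature_names[j] for j in ranking.order[:k]]


@dataclass(slots=True)
class AblationCurve:
    k_grid: list[int]
    error_at_k: list[float]
    elbow_k: int


def find_elbow(k_grid: Sequence[int], errors: Sequence[float]) -> int:
    """Knee of an error curve by normalized max chord distance.

    Both axes are min-max normalized, then the interior grid point with
    the largest perpendicular distance from the straight line joining the
    first and last points wins; ties go to the smallest k.
    """
    k = np.asarray(k_grid, dtype=float)
    e = np.asarray(errors, dtype=float)
    if len(k) < 3:
        raise ValueError("elbow detection needs at least 3 grid points")
    if not np.all(np.isfinite(e)):
        bad = int(k[np.flatnonzero(~np.isfinite(e))[0]])
        raise ValueError(f"non-finite error value at k={bad}")
    kn = (k - k[0]) / (k[-1] - k[0])
    span = e.max() - e.min()
    en = (e - e.min()) / span if span > 0 else np.zeros_like(e)
    # distance from chord (kn[0],en[0]) -> (kn[-1],en[-1]); endpoints excluded
    dx, dy = kn[-1] - kn[0], en[-1] - en[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (kn - kn[0]) - dx * (en - en[0])) / norm
    interior = np.arange(1, len(k) - 1)
    # ties (within float noise) go to the smallest k
    near_max = dist[interior] >= dist[interior].max() - 1e-12
    best = interior[np.flatnonzero(near_max)[0]]
    return int(k_grid[best])


def ablation_elbow(
    k_grid: Sequence[int], evaluate: Callable[[int], float]
) -> AblationCurve:
    """Evaluate model error across feature-set sizes and locate the elbow."""
    if list(k_grid) != sorted(set(k_grid)):
        raise ValueError("k_grid must be strictly increasing")
    errors = [float(evaluate(int(k))) for k in k_grid]
    return AblationCurve(
        k_grid=[int(k) for k in k_grid],
        error_at_k=errors,
        elbow_k=find_elbow(k_grid, errors),
    )
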