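"""Sample encoding and leave-one-out evaluation of biomarker feature sets.

Samples are encoded by any mix of pathway activity levels and individual
gene expression profiles, then scored with an instance-based probabilistic
classifier under leave-one-out cross-validation (LOOCV): for each held-out
sample, features are standardised with the remaining samples' statistics
only, and the sample receives a class-A score from a distance-weighted
nearest-neighbour rule with a Gaussian kernel over Euclidean distance whose
bandwidth is the median pairwise training distance.  The score is the
class-mean-normalised kernel mass,
``mean(w | class A) / (mean(w | class A) + mean(w | class B))``, so an
uninformative feature set scores every sample exactly 0.5 regardless of
fold-wise class imbalance.  This is an instance-based learner of the KStar
family (exponential similarity weighting over all training instances); the
scorer is pluggable so other instance-based rules can be substituted.

Discrimination is summarised by the area under the ROC curve in its
Mann-Whitney form: the fraction of (positive, negative) score pairs ranked
concordantly, ties credited 0.5.  ``evaluate_combinations`` exhaustively
evaluates every feature subset up to a size cap, supporting single-input
versus integrated biomarker model comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .activity import ActivityMatrix
from .formats import ExpressionDataset

__all__ = [
    "FeatureSet",
    "ClassifierConfig",
    "EvaluationResult",
    "encode_samples",
    "loocv_scores",
    "auc",
    "evaluate_combinations",
]

FeatureKind = Literal["pathway_activity", "gene_expr"]


@dataclass
class FeatureSet:
    """Samples x features matrix with per-feature kind tags and labels."""

    matrix: pd.DataFrame                       # samples x features
    kinds: list[FeatureKind]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        if self.matrix.shape[1] < 1:
            raise ValueError("feature set needs >= 1 feature")
        if len(self.kinds) != self.matrix.shape[1]:
            raise ValueError("one kind tag per feature column required")
        for kind in ("pathway_activity", "gene_expr"):
            names = [
                c for c, k in zip(self.matrix.columns, self.kinds) if k == kind
            ]
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate {kind} feature names")
        if not np.isfinite(self.matrix.to_numpy(dtype=float)).all():
            raise ValueError(
                "feature matrix contains non-finite values; impute or drop "
                "undefined activity cells before encoding"
            )
        missing = [s for s in self.matrix.index if s not in self.labels]
        if missing:
            raise ValueError(f"samples without labels: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.matrix.columns)

    def select(self, names: Sequence[str]) -> "FeatureSet":
        positions = [self.feature_names.index(n) for n in names]
        return FeatureSet(
            self.matrix.iloc[:, positions],
            [self.kinds[i] for i in positions],
            self.labels,
        )


@dataclass
class ClassifierConfig:
    """Instance-based scorer settings.

    ``bandwidth_rule`` maps the condensed pairwise training-distance vector
    to a kernel bandwidth; the default is its median, which is parameter
    free.  ``standardize`` z-scores each feature inside every LOOCV fold
    using the training samples only, so activity levels and raw gene
    expression can be mixed on one distance scale.
    """

    standardize: bool = True
    bandwidth_rule: Callable[[np.ndarray], float] = field(
        default=lambda d: float(np.median(d))
    )
    scorer: Literal["gaussian_knn"] = "gaussian_knn"


@dataclass
class EvaluationResult:
    per_sample_score: pd.Series       # probability-like score for class A
    auc: float
    feature_names: list[str]
    classifier_config: ClassifierConfig
    positive_class: str


def encode_samples(
    activity: ActivityMatrix,
    dataset: ExpressionDataset | None,
    pathway_names: Sequence[str] = (),
    gene_names: Sequence[str] = (),
    labels: dict[str, str] | None = None,
) -> FeatureSet:
    """Assemble a feature matrix from pathway activity columns and/or
    (collapsed) gene expression rows, in the requested order.

    ``labels`` defaults to the dataset's labels.  Unknown pathway or gene
    names raise ``KeyError`` listing every missing item.
    """
    if not pathway_names and not gene_names:
        raise ValueError("request at least one pathway or gene feature")
    missing = [p for p in pathway_names if p not in activity.activity.columns]
    if gene_names:
        if dataset is None:
            raise ValueError("gene features requested but no expression dataset given")
        missing += [g for g in gene_names if g not in dataset.values.index]
    if missing:
        raise KeyError(f"unknown feature name(s): {missing}")

    if labels is None:
        if dataset is None or dataset.labels is None:
            raise ValueError("labels required (none on the dataset)")
        labels = dataset.labels

    cols: list[pd.Series] = []
    kinds: list[FeatureKind] = []
    for p in pathway_names:
        cols.append(activity.activity[p])
        kinds.append("pathway_activity")
    for g in gene_names:
        row = dataset.values.loc[g]
        row = row.reindex(activity.sample_ids)
        cols.append(row.rename(g))
        kinds.append("gene_expr")
    matrix = pd.concat(cols, axis=1)
    matrix.index = pd.Index(activity.sample_ids)
    return FeatureSet(matrix, kinds, dict(labels))


# ---------------------------------------------------------------------------
# LOOCV instance-based scoring
# ---------------------------------------------------------------------------


def _fold_score(
    X_train: np.ndarray,
    y_train_is_a: np.ndarray,
    x_test: np.ndarray,
    config: ClassifierConfig,
) -> float:
    if config.standardize:
        mu = X_train.mean(axis=0)
        sd = X_train.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        X_train = (X_train - mu) / sd
        x_test = (x_test - mu) / sd
    # condensed pairwise training distances set the kernel bandwidth
    from scipy.spatial.distance import cdist, pdist

    h = config.bandwidth_rule(pdist(X_train))
    d = cdist(x_test[None, :], X_train)[0]
    if h > 0:
        w = np.exp(-(d * d) / (2.0 * h * h))
    else:
        # all training points coincide: no metric information, weight evenly
        w = np.ones_like(d)
    if w.sum() == 0:
        w = np.ones_like(d)
    # class-mean normalisation removes the leave-one-out class-prior
    # imbalance: with no metric information every sample scores exactly 0.5
    mean_a = w[y_train_is_a].mean()
    mean_b = w[~y_train_is_a].mean()
    if mean_a + mean_b == 0:
        return 0.5
    return float(mean_a / (mean_a + mean_b))


def loocv_scores(
    features: FeatureSet, config: ClassifierConfig | None = None
) -> EvaluationResult:
    """Leave-one-out class-A scores plus AUC for a feature set.

    Each sample is scored by a model that never saw it: per-fold feature
    standardisation and the kernel bandwidth are computed from the training
    samples alone.  Classes with fewer than two samples make LOOCV
    ill-posed and raise ``ValueError``.
    """
    config = config or ClassifierConfig()
    X = features.matrix.to_numpy(dtype=float)
    samples = features.sample_ids
    lab = [features.labels[s] for s in samples]
    classes: list[str] = []
    for l in lab:
        if l not in classes:
            classes.append(l)
    if len(classes) != 2:
        raise ValueError(f"exactly 2 classes required, got {classes}")
    positive = classes[0]
    y_is_a = np.array([l == positive for l in lab])
    if y_is_a.sum() < 2 or (~y_is_a).sum() < 2:
        raise ValueError("LOOCV needs >= 2 samples per class")

    n = len(samples)
    scores = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        scores[i] = _fold_score(X[keep], y_is_a[keep], X[i], config)

    score_series = pd.Series(scores, index=samples, name="class_a_score")
    return EvaluationResult(
        per_sample_score=score_series,
        auc=auc(score_series, features.labels, positive=positive),
        feature_names=features.feature_names,
        classifier_config=config,
        positive_class=positive,
    )


# ---------------------------------------------------------------------------
# AUC (Mann-Whitney form)
# ---------------------------------------------------------------------------


def auc(
    scores: pd.Series | Sequence[float],
    labels: dict[str, str] | Sequence[str],
    positive: str | None = None,
) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    ``AUC = (concordant + 0.5 * tied) / (n_pos * n_neg)`` over all
    (positive, negative) score pairs.  ``positive`` defaults to the first
    label encountered.  One-class input is an error.
    """
    if isinstance(scores, pd.Series):
        s = scores.to_numpy(dtype=float)
        if isinstance(labels, dict):
            lab = [labels[i] for i in scores.index]
        else:
            lab = list(labels)
    else:
        s = np.asarray(scores, dtype=float)
        lab = list(labels.values()) if isinstance(labels, dict) else list(labels)
    if len(s) != len(lab):
        raise ValueError("scores and labels differ in length")
    classes = sorted(set(lab), key=lab.index)
    if len(classes) != 2:
        raise ValueError(f"AUC requires exactly 2 classes, got {classes}")
    if positive is None:
        positive = classes[0]
    elif positive not in classes:
        raise ValueError(f"positive class {positive!r} not among {classes}")
    is_pos = np.array([l == positive for l in lab])

    from scipy.stats import rankdata

    ranks = rankdata(s)  # midranks implement the 0.5 tie credit exactly
    n_pos = int(is_pos.sum())
    n_neg = len(s) - n_pos
    u = ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# combination sweep
# ---------------------------------------------------------------------------


def evaluate_combinations(
    features: FeatureSet,
    max_size: int = 2,
    config: ClassifierConfig | None = None,
    size_guard: int = 4,
) -> pd.DataFrame:
    """LOOCV AUC for every non-empty feature subset of size <= ``max_size``.

    Output columns: ``features`` (comma-joined names), ``n_features``,
    ``auc``; sorted by AUC descending, then smaller subsets first, then
    lexicographic names.  ``size_guard`` caps the exhaustive sweep (the
    subset count explodes combinatorially); raise it explicitly for larger
    panels.
    """
    n = len(features.feature_names)
    if max_size < 1 or max_size > n:
        raise ValueError(f"max_size must be in 1..{n}, got {max_size}")
    if max_size > size_guard:
        raise ValueError(
            f"max_size={max_size} exceeds the combinatorial guard "
            f"({size_guard}); pass size_guard explicitly to override"
        )
    rows = []
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(features.feature_names, size):
            result = loocv_scores(features.select(combo), config)
            rows.append(
                {"features": ",".join(combo), "n_features": size, "auc": result.auc}
            )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["auc", "n_features", "features"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return table
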