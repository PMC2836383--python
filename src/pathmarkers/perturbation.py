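"""Pathway perturbation scoring and permutation calibration.

A pathway's perturbation score is the unsigned two-sample t-statistic
comparing its per-sample activity levels between the two classes (pooled-
variance Student form by default; Welch selectable).  Statistical
significance is calibrated by permuting the class labels: the same set of
random permutations (class sizes preserved automatically, since a label
multiset is permuted) is applied to every pathway, and each pathway's
p-value is the proportion of null scores at least as large as its observed
score, with add-one smoothing ``(c + 1) / (B + 1)`` so p is never 0 and is
floored at ``1 / (B + 1)``.  An exhaustive mode enumerates all distinct
binary label assignments instead (feasible for small cohorts only) and
returns the exact proportion ``c' / T`` including the observed assignment.

Degenerate columns follow two rules: zero within-class variance with a zero
mean difference scores 0; zero variance with a non-zero difference scores
+inf and ranks above every finite score.  Columns with fewer than two
defined values in either class are unscorable and are excluded from the
ranking with a warning.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .activity import ActivityMatrix
from .formats import PathwayCollection

__all__ = [
    "perturbation_score",
    "column_statistics",
    "permutation_pvalues",
    "rank_pathways",
    "score_pathways",
    "overlap_graph",
]

TVariant = Literal["pooled", "welch"]


# ---------------------------------------------------------------------------
# t-statistics, vectorised over pathway columns
# ---------------------------------------------------------------------------


def _t_columns(
    L: np.ndarray, mask_a: np.ndarray, variant: TVariant = "pooled"
) -> np.ndarray:
    """Signed two-sample t for every column of ``L`` (samples x pathways).

    ``mask_a`` is a boolean matrix (n_assignments x n_samples); one t value
    per (assignment, column) pair is returned.  NaN cells of ``L`` are
    excluded from both groups.  Columns with < 2 defined values in either
    group give NaN; the degenerate zero-variance rules give 0 or +-inf.
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    mask_a = np.atleast_2d(np.asarray(mask_a, dtype=bool))
    defined = ~np.isnan(L)
    V = np.where(defined, L, 0.0)
    V2 = V * V
    D = defined.astype(float)

    MA = mask_a.astype(float)
    MB = (~mask_a).astype(float)

    nA = MA @ D
    nB = MB @ D
    sA = MA @ V
    sB = MB @ V
    qA = MA @ V2
    qB = MB @ V2

    with np.errstate(divide="ignore", invalid="ignore"):
        mA = sA / nA
        mB = sB / nB
        ssA = qA - nA * mA * mA   # within-group sums of squared deviations
        ssB = qB - nB * mB * mB
        ssA = np.maximum(ssA, 0.0)  # clamp negative rounding residue
        ssB = np.maximum(ssB, 0.0)
        diff = mA - mB
        if variant == "pooled":
            sp2 = (ssA + ssB) / (nA + nB - 2)
            se = np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
        elif variant == "welch":
            se = np.sqrt(ssA / (nA * (nA - 1)) + ssB / (nB * (nB - 1)))
        else:
            raise ValueError(f"unknown t variant: {variant!r}")
        t = diff / se

    # degenerate rules where the standard error vanished
    with np.errstate(invalid="ignore"):
        zero_se = se == 0
        t = np.where(zero_se & (diff == 0), 0.0, t)
        t = np.where(zero_se & (diff != 0), np.sign(diff) * np.inf, t)
        # unscorable: fewer than 2 defined values in either group
        t = np.where((nA < 2) | (nB < 2), np.nan, t)
    return t


def perturbation_score(
    values: Sequence[float],
    labels: Sequence[str],
    variant: TVariant = "pooled",
) -> tuple[float, float]:
    """Score one pathway column: ``(t_signed, score)`` with score = |t|.

    ``t_signed`` is class A minus class B, where class A is the
    lexicographically smaller label (so exchanging the two labels flips the
    sign and leaves the unsigned score unchanged).  Requires >= 2 defined
    values per class.
    """
    values = np.asarray(values, dtype=float)
    labels = list(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels differ in length")
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"exactly 2 classes required, got {classes}")
    mask_a = np.array([lab == classes[0] for lab in labels])
    t = float(_t_columns(values.reshape(-1, 1), mask_a.reshape(1, -1), variant)[0, 0])
    if math.isnan(t):
        raise ValueError("fewer than 2 defined values in one of the classes")
    return t, abs(t)


def column_statistics(
    activity: ActivityMatrix,
    labels: dict[str, str],
    variant: TVariant = "pooled",
) -> pd.DataFrame:
    """Observed signed t and unsigned score for every pathway column.

    Returns a DataFrame indexed by pathway name with columns ``t_signed``,
    ``score`` and ``n_defined``; unscorable pathways carry NaN.
    """
    mask_a, _ = _class_mask(activity, labels)
    L = activity.activity.to_numpy(dtype=float)
    t = _t_columns(L, mask_a[None, :])[0]
    return pd.DataFrame(
        {
            "t_signed": t,
            "score": np.abs(t),
            "n_defined": (~np.isnan(L)).sum(axis=0),
        },
        index=activity.pathway_names,
    )


def _class_mask(
    activity: ActivityMatrix, labels: dict[str, str]
) -> tuple[np.ndarray, tuple[str, str]]:
    sample_ids = activity.sample_ids
    missing = [s for s in sample_ids if s not in labels]
    if missing:
        raise ValueError(f"samples without labels: {missing}")
    seen = sorted({labels[s] for s in sample_ids})
    if len(seen) != 2:
        raise ValueError(f"exactly 2 classes required, got {seen}")
    mask_a = np.array([labels[s] == seen[0] for s in sample_ids])
    return mask_a, (seen[0], seen[1])


# ---------------------------------------------------------------------------
# permutation p-values
# ---------------------------------------------------------------------------


def permutation_pvalues(
    activity: ActivityMatrix,
    labels: dict[str, str],
    B: int = 10_000,
    seed: int = 0,
    mode: Literal["sampled", "exhaustive"] = "sampled",
    variant: TVariant = "pooled",
    max_exhaustive_samples: int = 20,
) -> pd.Series:
    """Per-pathway permutation p-values for the unsigned perturbation score.

    ``sampled``: B random label permutations, shared across pathways, with
    ``p = (c + 1) / (B + 1)`` where c counts null scores >= the observed
    score.  ``exhaustive``: all C(n, n_A) distinct assignments,
    ``p = c' / T`` with the observed assignment included in both c' and T.
    A fixed seed makes sampled mode bit-reproducible.  Unscorable pathways
    get NaN.
    """
    mask_obs, _ = _class_mask(activity, labels)
    L = activity.activity.to_numpy(dtype=float)
    n_samples = L.shape[0]
    t_obs = _t_columns(L, mask_obs[None, :], variant)[0]
    score_obs = np.abs(t_obs)

    if mode == "exhaustive":
        if n_samples > max_exhaustive_samples:
            raise ValueError(
                f"exhaustive mode limited to {max_exhaustive_samples} samples "
                f"(got {n_samples}); raise max_exhaustive_samples to override"
            )
        n_a = int(mask_obs.sum())
        masks = np.zeros(
            (math.comb(n_samples, n_a), n_samples), dtype=bool
        )
        for r, pos in enumerate(itertools.combinations(range(n_samples), n_a)):
            masks[r, list(pos)] = True
        null_scores = np.abs(_t_columns(L, masks, variant))
        with np.errstate(invalid="ignore"):
            c = (null_scores >= score_obs[None, :]).sum(axis=0)
        p = c / masks.shape[0]
    else:
        if B < 1:
            raise ValueError("B must be >= 1 for sampled mode")
        rng = np.random.default_rng(seed)
        masks = np.empty((B, n_samples), dtype=bool)
        for b in range(B):
            masks[b] = rng.permutation(mask_obs)
        null_scores = np.abs(_t_columns(L, masks, variant))
        with np.errstate(invalid="ignore"):
            c = (null_scores >= score_obs[None, :]).sum(axis=0)
        p = (c + 1) / (B + 1)

    p = np.where(np.isnan(score_obs), np.nan, p)
    return pd.Series(p, index=activity.pathway_names, name="p_value")


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


def rank_pathways(scores: pd.DataFrame) -> pd.DataFrame:
    """Rank pathways by descending unsigned score.

    ``scores`` is indexed by pathway name with at least ``t_signed``,
    ``score`` and ``p_value`` columns.  Ties on score break by ascending
    p-value, then lexicographic pathway name.  Unscorable rows (NaN score)
    are dropped with a warning.  Returns the table sorted, with a ``rank``
    column numbered from 1.
    """
    unscorable = scores.index[scores["score"].isna()].tolist()
    if unscorable:
        warnings.warn(
            f"{len(unscorable)} unscorable pathway(s) excluded from ranking: "
            f"{unscorable[:5]}{'...' if len(unscorable) > 5 else ''}",
            stacklevel=2,
        )
    table = scores.dropna(subset=["score"]).copy()
    if table.empty:
        raise ValueError("no scorable pathway to rank")
    table = _sorted_table(table)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def _sorted_table(table: pd.DataFrame) -> pd.DataFrame:
    order = sorted(
        range(len(table)),
        key=lambda i: (
            -table["score"].iloc[i],
            table["p_value"].iloc[i] if not math.isnan(table["p_value"].iloc[i]) else math.inf,
            table.index[i],
        ),
    )
    return table.iloc[order]


def score_pathways(
    activity: ActivityMatrix,
    labels: dict[str, str],
    B: int = 10_000,
    seed: int = 0,
    mode: Literal["sampled", "exhaustive"] = "sampled",
    variant: TVariant = "pooled",
    n_genes_in_data: pd.Series | None = None,
) -> pd.DataFrame:
    """Full perturbation table: observed t, score, permutation p and rank.

    Convenience wrapper chaining :func:`column_statistics`,
    :func:`permutation_pvalues` and :func:`rank_pathways`.
    """
    stats = column_statistics(activity, labels, variant)
    stats["p_value"] = permutation_pvalues(
        activity, labels, B=B, seed=seed, mode=mode, variant=variant
    )
    if n_genes_in_data is not None:
        stats["n_genes_in_data"] = n_genes_in_data
    else:
        stats["n_genes_in_data"] = activity.n_genes_used.max(axis=0)
    return rank_pathways(stats)


# ---------------------------------------------------------------------------
# pathway overlap graph
# ---------------------------------------------------------------------------


def overlap_graph(
    collection: PathwayCollection, subset: Sequence[str] | None = None
) -> nx.Graph:
    """Undirected graph over pathways with an edge wherever two gene sets
    share at least one gene; isolated pathways keep their node.

    Edge attribute ``shared_genes`` carries the intersection.  Unknown names
    in ``subset`` raise ``KeyError``.
    """
    if subset is None:
        chosen = list(collection)
    else:
        chosen = list(collection.subset(subset))
    g = nx.Graph()
    for p in chosen:
        g.add_node(p.name, n_genes=len(p.genes))
    for p, q in itertools.combinations(chosen, 2):
        shared = p.genes & q.genes
        if shared:
            g.add_edge(p.name, q.name, shared_genes=set(shared), n_shared=len(shared))
    return g


def write_edge_list(graph: nx.Graph, path) -> None:
    """Export the overlap graph as an edge-list TSV (isolated nodes listed
    in a trailing comment-free section with an empty partner column)."""
    from pathlib import Path

    lines = ["pathway_a\tpathway_b\tn_shared\tshared_genes"]
    for a, b, data in sorted(graph.edges(data=True)):
        genes = ",".join(sorted(data["shared_genes"]))
        lines.append(f"{a}\t{b}\t{data['n_shared']}\t{genes}")
    for node in sorted(graph.nodes):
        if graph.degree(node) == 0:
            lines.append(f"{node}\t\t0\t")
    Path(path).write_text("\n".join(lines) + "\n")
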