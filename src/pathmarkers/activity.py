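"""Per-sample pathway activity levels.

For a sample *i* and pathway *k* the activity level is the arithmetic mean
of the expression values of the pathway's member genes that are actually
measured in the matrix (present as a row and non-NaN for that sample).
Pathways with no measured member gene at all are filtered out before any
scoring; a (sample, pathway) cell whose measured-gene count happens to be
zero while the pathway is measured in other samples is flagged undefined
(NaN) and excluded from downstream statistics.

Gene matching between gene sets and expression rows is exact string match
after upper-casing both sides by default (``match_case=True`` turns the
normalisation off), since gene-set symbols are conventionally upper case
while platform row ids vary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import ExpressionDataset, PathwayCollection

__all__ = [
    "ActivityMatrix",
    "filter_measured_pathways",
    "compute_activity",
    "count_instances",
]


@dataclass
class ActivityMatrix:
    """Samples x pathways activity levels.

    ``activity[i, k]`` is NaN where ``n_genes_used[i, k] == 0`` (no measured
    member gene for that sample) and finite everywhere else.
    """

    activity: pd.DataFrame          # samples x pathways, float
    n_genes_used: pd.DataFrame      # samples x pathways, int

    @property
    def sample_ids(self) -> list[str]:
        return list(self.activity.index)

    @property
    def pathway_names(self) -> list[str]:
        return list(self.activity.columns)

    @property
    def n_samples(self) -> int:
        return self.activity.shape[0]

    @property
    def n_pathways(self) -> int:
        return self.activity.shape[1]


def _gene_index(dataset: ExpressionDataset, match_case: bool) -> dict[str, int]:
    """Map (normalised) gene symbol -> row position; first row wins on clash.

    Case-insensitive duplicate rows should normally be collapsed first with
    :func:`pathmarkers.formats.collapse_duplicate_genes`.
    """
    index: dict[str, int] = {}
    for pos, g in enumerate(dataset.gene_ids):
        key = g if match_case else g.upper()
        index.setdefault(key, pos)
    return index


def filter_measured_pathways(
    collection: PathwayCollection,
    dataset: ExpressionDataset,
    match_case: bool = False,
) -> tuple[PathwayCollection, list[str]]:
    """Split a collection into pathways with >= 1 gene measured in the matrix
    and those with none.

    Returns ``(retained, dropped_names)`` with the original order preserved.
    An empty retained set is a hard error: no pathway overlaps the data.
    """
    index = _gene_index(dataset, match_case)
    retained = []
    dropped: list[str] = []
    for p in collection:
        genes = p.genes if match_case else {g.upper() for g in p.genes}
        if any(g in index for g in genes):
            retained.append(p)
        else:
            dropped.append(p.name)
    if not retained:
        raise ValueError("no pathway overlaps the expression data")
    return PathwayCollection(retained), dropped


def compute_activity(
    dataset: ExpressionDataset,
    collection: PathwayCollection,
    match_case: bool = False,
) -> ActivityMatrix:
    """Compute the samples x pathways activity matrix.

    The collection should already have been passed through
    :func:`filter_measured_pathways`; pathways without any measured gene
    yield an all-NaN column rather than an error, so the filter is advisory
    for this function but required by downstream scoring.
    """
    if dataset.n_samples < 1:
        raise ValueError("dataset has no samples")
    index = _gene_index(dataset, match_case)
    values = dataset.values.to_numpy(dtype=float)          # genes x samples
    measured = ~np.isnan(values)

    n_samples = dataset.n_samples
    L = np.full((n_samples, len(collection)), np.nan)
    counts = np.zeros((n_samples, len(collection)), dtype=int)

    for k, p in enumerate(collection):
        genes = p.genes if match_case else {g.upper() for g in p.genes}
        rows = sorted(index[g] for g in genes if g in index)
        if not rows:
            continue
        sub = values[rows, :]                              # members x samples
        sub_measured = measured[rows, :]
        n_used = sub_measured.sum(axis=0)
        with np.errstate(invalid="ignore"):
            sums = np.where(sub_measured, sub, 0.0).sum(axis=0)
            col = np.where(n_used > 0, sums / np.maximum(n_used, 1), np.nan)
        L[:, k] = col
        counts[:, k] = n_used

    sample_ids = dataset.sample_ids
    names = collection.names
    return ActivityMatrix(
        activity=pd.DataFrame(L, index=sample_ids, columns=names),
        n_genes_used=pd.DataFrame(counts, index=sample_ids, columns=names),
    )


def count_instances(activity: ActivityMatrix) -> int:
    """Number of (sample, pathway) instances = samples x pathways."""
    return activity.n_samples * activity.n_pathways
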