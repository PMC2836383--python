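"""Synthetic two-class expression datasets with planted pathway effects.

The generator emulates the shape of a processed two-class microarray
study: a genes x samples matrix of log-scale intensities with Gaussian
per-gene noise around per-gene baselines, a collection of gene sets of
configurable sizes and cross-set overlap, a configurable number of
"planted" pathways whose member genes receive a mean shift in class A, and
optionally extra gene sets built entirely from identifiers absent from the
matrix (so the >= 1-measured-gene pathway filter has something to drop).

The defaults reproduce the reference study design: 32 samples (16 per
class), 639 pathways of which 2 are unmeasured, leaving 637 scorable.

All randomness flows from one seed through named sub-streams (membership,
baselines, noise), so e.g. changing the number of samples does not perturb
pathway membership.  Identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import ExpressionDataset, Pathway, PathwayCollection

__all__ = ["SimulationConfig", "GroundTruth", "simulate_dataset"]


@dataclass
class SimulationConfig:
    """Knobs for the synthetic study.

    ``effect_size`` is the additive mean shift (expression units, i.e.
    log-scale) applied in class A to every gene belonging to a planted
    pathway; ``noise_sd`` is the per-gene Gaussian noise SD on the same
    scale.  ``gene_overlap_fraction`` is the fraction of each pathway's
    genes preferentially drawn from genes already used by earlier pathways,
    controlling how much the sets share members.
    """

    n_genes: int = 25_000
    n_samples_per_class: tuple[int, int] = (16, 16)
    n_pathways: int = 639          # total, INCLUDING the unmeasured sets
    pathway_size_range: tuple[int, int] = (10, 100)
    n_planted: int = 10
    effect_size: float = 1.0
    noise_sd: float = 1.0
    n_unmeasured_pathways: int = 2
    gene_overlap_fraction: float = 0.1
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    class_names: tuple[str, str] = ("VDpos", "VDneg")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_pathways < 1:
            raise ValueError("n_genes and n_pathways must be positive")
        if min(self.n_samples_per_class) < 1:
            raise ValueError("both classes need >= 1 sample")
        lo, hi = self.pathway_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid pathway_size_range")
        if hi > self.n_genes:
            raise ValueError(
                f"pathway_size_range upper bound {hi} exceeds n_genes {self.n_genes}"
            )
        if self.n_unmeasured_pathways >= self.n_pathways:
            raise ValueError("n_unmeasured_pathways must be < n_pathways")
        if not 0 <= self.n_planted <= self.n_measured_pathways:
            raise ValueError("n_planted must be in 0..(n_pathways - n_unmeasured)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.gene_overlap_fraction <= 1.0:
            raise ValueError("gene_overlap_fraction must be in [0, 1]")
        if self.n_unmeasured_pathways < 0:
            raise ValueError("n_unmeasured_pathways must be >= 0")

    @property
    def n_measured_pathways(self) -> int:
        return self.n_pathways - self.n_unmeasured_pathways


@dataclass
class GroundTruth:
    planted: list[str]
    gene_shift: dict[str, float]       # per-gene true class-A mean shift
    labels: dict[str, str]
    unmeasured: list[str] = field(default_factory=list)


def _pathway_memberships(config: SimulationConfig, rng: np.random.Generator):
    """Sample gene memberships for the measured pathways.

    A configurable fraction of each set is drawn from genes already used by
    earlier sets (when available), the remainder from the untouched pool,
    producing controllable cross-set overlap.
    """
    lo, hi = config.pathway_size_range
    used: list[int] = []
    used_set: set[int] = set()
    memberships: list[np.ndarray] = []
    for _ in range(config.n_measured_pathways):
        size = int(rng.integers(lo, hi + 1))
        n_shared = min(int(round(config.gene_overlap_fraction * size)), len(used))
        chosen: set[int] = set()
        if n_shared > 0:
            chosen.update(
                rng.choice(np.asarray(used), size=n_shared, replace=False).tolist()
            )
        while len(chosen) < size:
            g = int(rng.integers(0, config.n_genes))
            chosen.add(g)
        members = np.array(sorted(chosen))
        memberships.append(members)
        for g in members:
            if g not in used_set:
                used_set.add(g)
                used.append(g)
    return memberships


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, PathwayCollection, GroundTruth]:
    """Generate ``(dataset, collection, truth)`` from a config.

    Baseline expression of gene g in every sample is
    ``Normal(mu_g, noise_sd^2)`` with ``mu_g ~ Normal(baseline_mean,
    baseline_sd^2)`` drawn once; genes in planted pathways get
    ``+effect_size`` in class A.  Unmeasured pathways are appended after
    the measured ones and built from gene ids absent from the matrix.
    """
    ss = np.random.SeedSequence(config.seed)
    membership_rng, baseline_rng, noise_rng = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )

    n_a, n_b = config.n_samples_per_class
    n_samples = n_a + n_b
    class_a, class_b = config.class_names
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    labels = {
        s: (class_a if i < n_a else class_b) for i, s in enumerate(sample_ids)
    }
    gene_ids = [f"G{g + 1:05d}" for g in range(config.n_genes)]

    memberships = _pathway_memberships(config, membership_rng)
    planted_idx = (
        membership_rng.choice(
            config.n_measured_pathways, size=config.n_planted, replace=False
        )
        if config.n_planted
        else np.array([], dtype=int)
    )
    planted_idx = np.sort(planted_idx)

    shifted_genes: set[int] = set()
    for k in planted_idx:
        shifted_genes.update(memberships[k].tolist())

    mu = baseline_rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    values = mu[:, None] + noise_rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, n_samples)
    )
    if shifted_genes and config.effect_size > 0:
        rows = np.array(sorted(shifted_genes))
        values[np.ix_(rows, np.arange(n_a))] += config.effect_size

    dataset = ExpressionDataset(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), labels
    )

    entries = [
        Pathway(
            name=f"PW{k + 1:04d}",
            description="planted" if k in set(planted_idx.tolist()) else "background",
            genes=frozenset(gene_ids[g] for g in memberships[k]),
        )
        for k in range(config.n_measured_pathways)
    ]
    unmeasured_names = []
    for j in range(config.n_unmeasured_pathways):
        name = f"PW_UNMEASURED{j + 1:02d}"
        unmeasured_names.append(name)
        entries.append(
            Pathway(
                name=name,
                description="unmeasured",
                genes=frozenset(f"ABSENT{j + 1:02d}_{i}" for i in range(5)),
            )
        )
    collection = PathwayCollection(entries)

    truth = GroundTruth(
        planted=[f"PW{k + 1:04d}" for k in planted_idx],
        gene_shift={
            gene_ids[g]: (config.effect_size if g in shifted_genes else 0.0)
            for g in range(config.n_genes)
        },
        labels=dict(labels),
        unmeasured=unmeasured_names,
    )
    return dataset, collection, truth
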