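import numpy as np
import pandas as pd
import pytest

from pathmarkers import (
    ExpressionDataset,
    Pathway,
    PathwayCollection,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """4 genes x 4 samples, 2 classes, one missing cell (g2 in s1)."""
    values = pd.DataFrame(
        [
            [1.0, 2.0, 3.0, 4.0],
            [np.nan, 6.0, 7.0, 8.0],
            [2.0, 2.0, 2.0, 2.0],
            [10.0, 9.0, 1.0, 2.0],
        ],
        index=["G1", "G2", "G3", "G4"],
        columns=["s1", "s2", "s3", "s4"],
    )
    labels = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
    return ExpressionDataset(values, labels)


@pytest.fixture
def tiny_collection() -> PathwayCollection:
    return PathwayCollection(
        [
            Pathway("P1", "na", frozenset({"G1", "G2"})),
            Pathway("P2", "na", frozenset({"G3", "G4"})),
            Pathway("P3", "na", frozenset({"G4"})),
            Pathway("P_ABSENT", "na", frozenset({"Z1", "Z2"})),
        ]
    )


@pytest.fixture
def small_simulation():
    """A quick synthetic study with a strong planted effect."""
    config = SimulationConfig(
        n_genes=600,
        n_samples_per_class=(8, 8),
        n_pathways=40,
        pathway_size_range=(5, 15),
        n_planted=2,
        effect_size=3.0,
        noise_sd=1.0,
        n_unmeasured_pathways=2,
        gene_overlap_fraction=0.1,
        seed=42,
    )
    return simulate_dataset(config)
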