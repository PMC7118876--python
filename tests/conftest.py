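from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metaconcord import (
    FunctionalHierarchy,
    GeneTable,
    StudyMetadata,
    SyntheticConfig,
    align_pair,
    generate_paired_study,
    normalize,
)


def make_table(values, genes=None, samples=None) -> GeneTable:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"K{i + 1:05d}" for i in range(values.shape[0])]
    samples = samples or [f"S{i + 1}" for i in range(values.shape[1])]
    return GeneTable(pd.DataFrame(values, index=genes, columns=samples))


@pytest.fixture
def small_table() -> GeneTable:
    return make_table([[2.0, 1.0], [2.0, 3.0], [0.0, 1.0]])


@pytest.fixture
def two_group_metadata() -> StudyMetadata:
    return StudyMetadata(
        {f"S{i + 1}": ("g1" if i < 5 else "g2") for i in range(10)}, ("g1", "g2")
    )


@pytest.fixture
def simple_hierarchy() -> FunctionalHierarchy:
    return FunctionalHierarchy(
        {
            "K00001": {("Metabolism", "Amino acid metabolism")},
            "K00002": {("Metabolism", "Carbohydrate metabolism")},
            "K00003": {
                ("Metabolism", "Amino acid metabolism"),
                ("Genetic Information Processing", "Translation"),
            },
        }
    )


@pytest.fixture(scope="session")
def default_study():
    """One medium synthetic study shared by read-only tests."""
    return generate_paired_study(
        SyntheticConfig(
            n_genes=400,
            n_samples_per_group=10,
            n_differential=60,
            concordance=0.9,
            miss_fraction=0.1,
            spurious_fraction=0.1,
            seed=42,
        )
    )


@pytest.fixture(scope="session")
def default_pair(default_study):
    return align_pair(default_study.predicted, default_study.observed)
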