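"""Shared fixtures: a small synthetic dataset reused across test modules."""

import pandas as pd
import pytest

from vepmeta import metrics as met
from vepmeta import synthetic as syn
from vepmeta.variant_io import apply_quality_filters, build_gene_dataset


@pytest.fixture(scope="session")
def small_config():
    return syn.SyntheticConfig(n_genes=40, length_range=(150, 400), seed=3)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return syn.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_gene_dataset(small_dataset):
    """Quality-filtered, eligibility-checked dataset built from the fixture."""
    ds = small_dataset
    pathogenic = ds.variants[ds.variants["class_label"] == "pathogenic"]
    benign = ds.variants[ds.variants["class_label"] == "benign"]
    benign_mis = apply_quality_filters(benign[benign["consequence"] == "missense"])
    benign_all = pd.concat(
        [benign_mis, benign[benign["consequence"] == "nonsense"]], ignore_index=True
    )
    return build_gene_dataset(pathogenic, benign_all, ds.scores, ds.orientation)


@pytest.fixture(scope="session")
def small_performance(small_dataset, small_gene_dataset):
    return met.per_gene_performance(
        small_gene_dataset, small_dataset.scores, small_dataset.genes
    )
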