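"""Shared fixtures: small simulated datasets with known ground truth."""

import pandas as pd
import pytest

from translatome.quantify import ExpressionSet, filter_detected, rpkm
from translatome.simulate import (
    SimConfig,
    generate_annotation,
    generate_truth,
    simulate_counts,
)

#: truth class -> (category, direction) expected from the classifier
CLASS_MAP = {
    "translation_up": ("translation_driven", "up"),
    "synergistic_up": ("synergistic", "up"),
    "rna_up": ("rna_driven", "up"),
    "translation_down": ("translation_driven", "down"),
    "synergistic_down": ("synergistic", "down"),
    "rna_down": ("rna_driven", "down"),
}


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_genes=400, n_families=10, targets_per_family=40, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(config, genes, truth, counts) for a 400-gene, full-design simulation."""
    genes = generate_annotation(small_config)
    truth = generate_truth(genes, small_config)
    counts = simulate_counts(truth, genes, small_config)
    return small_config, genes, truth, counts


@pytest.fixture(scope="session")
def small_rpkm(small_dataset):
    _, genes, _, counts = small_dataset
    detected = filter_detected(counts)
    return rpkm(counts.subset_genes(detected), genes)


def make_expression(frame: pd.DataFrame, unit: str = "counts") -> ExpressionSet:
    return ExpressionSet.from_matrix(frame, unit=unit)
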