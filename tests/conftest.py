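"""Shared fixtures: a small synthetic study and its pipeline run."""

import numpy as np
import pytest
from hypothesis import settings

from citsift import PipelineConfig, SimConfig, generate_dataset, run_pipeline
from citsift.expression import ExpressionMatrix

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """An 80-gene study with one planted exporter (fixed seed)."""
    return generate_dataset(SimConfig(n_genes=80, seed=42))


@pytest.fixture(scope="session")
def small_result(small_dataset):
    return run_pipeline(small_dataset, PipelineConfig())


@pytest.fixture
def tiny_matrix():
    """Two genes, two conditions x two replicates, hand-made counts."""
    return ExpressionMatrix(
        gene_ids=["gA", "gB"],
        counts=np.array([[100, 120, 400, 380], [900, 880, 600, 620]]),
        sample_names=[
            "NW305_minusFe_a_r1",
            "NW305_minusFe_a_r2",
            "NW186_minusFe_a_r1",
            "NW186_minusFe_a_r2",
        ],
        sample_conditions=[
            "NW305 -Fe_a",
            "NW305 -Fe_a",
            "NW186 -Fe_a",
            "NW186 -Fe_a",
        ],
        gene_lengths=np.array([1000, 2000]),
        read_length=100,
    )
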