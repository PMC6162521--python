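import numpy as np
import pandas as pd
import pytest

from tissueclf import (
    ExpressionMatrix,
    SampleLabels,
    SyntheticSpec,
    generate_dataset,
)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes × 4 samples with one all-zero gene."""
    data = pd.DataFrame(
        [[1.0, 0.0, 2.5, 3.0], [0.0, 0.0, 0.0, 0.0], [4.0, 4.0, 4.0, 4.0]],
        index=pd.Index(["G1", "G2", "G3"], name="Name"),
        columns=["S1", "S2", "S3", "S4"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def tiny_labels() -> SampleLabels:
    return SampleLabels({"S1": "A", "S2": "A", "S3": "B", "S4": "B"}, ["A", "B"])


@pytest.fixture(scope="session")
def small_planted():
    """A fast 6-tissue dataset with 10 planted quantitative genes.

    Session-scoped: the generator is deterministic, and several modules probe
    the same planted structure.
    """
    spec = SyntheticSpec(
        n_tissues=6,
        samples_per_tissue=[12] * 6,
        n_quant_genes=10,
        n_enriched_genes=6,
        n_noise_genes=120,
        effect_sd=1.5,
        seed=11,
    )
    return generate_dataset(spec)


def random_confusion_labels(rng: np.random.Generator, n: int, n_classes: int):
    """Random (true, predicted) label vectors covering all classes."""
    tags = [f"C{j}" for j in range(n_classes)]
    true = rng.choice(tags, size=n)
    true[:n_classes] = tags  # every class represented
    pred = rng.choice(tags, size=n)
    return list(true), list(pred), tags
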