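import numpy as np
import pandas as pd
import pytest

from crossclock.datasets import CountDataset
from crossclock.simulate import SimConfig, simulate_dataset


def make_dataset(counts, ages, unit="years", studies=None, species="species_a"):
    """Small hand-rolled CountDataset from a genes x samples array."""
    counts = np.asarray(counts)
    g, s = counts.shape
    gene_ids = [f"g{i + 1:03d}" for i in range(g)]
    sample_ids = [f"s{j + 1:02d}" for j in range(s)]
    meta = pd.DataFrame(
        {
            "study_id": studies if studies is not None else ["st1"] * s,
            "age": ages,
            "age_unit": unit,
            "species": species,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CountDataset(
        counts=pd.DataFrame(counts.astype(np.int64), index=gene_ids, columns=sample_ids),
        metadata=meta,
    )


@pytest.fixture
def tiny_dataset():
    rng = np.random.default_rng(7)
    counts = rng.poisson(50, size=(30, 8))
    ages = np.linspace(20, 80, 8)
    return make_dataset(counts, ages, studies=["st1"] * 4 + ["st2"] * 4)


def small_config(seed=0, **overrides):
    """Scaled-down simulation for unit tests (fast, same structure)."""
    params = dict(
        n_genes_a=400,
        n_genes_b=400,
        n_samples_per_study_a=(10, 10, 10),
        n_samples_per_study_b=(10, 10, 10),
        n_conserved_pairs=20,
        n_private_aging_a=10,
        n_private_aging_b=10,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_dataset(small_config(seed=11))
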