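import numpy as np
import pandas as pd
import pytest

from coretempo import OtuTable


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


def random_table(rng, n_samples=10, n_otus=20, max_count=30, zero_frac=0.4):
    """Small random count table with plenty of structural zeros."""
    counts = rng.integers(1, max_count, size=(n_samples, n_otus))
    counts[rng.random((n_samples, n_otus)) < zero_frac] = 0
    counts[:, 0] += 1  # keep every sample non-empty
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"otu{j}" for j in range(n_otus)],
        )
    )


@pytest.fixture
def small_table(rng):
    return random_table(rng)


@pytest.fixture
def four_phylum_taxonomy():
    """Taxonomy for otu0..otu19 cycling through four phyla, full lineages."""
    phyla = ["Firmicutes", "Bacteroidetes", "Actinobacteria", "Verrucomicrobia"]
    rows = {}
    for j in range(20):
        p = phyla[j % 4]
        rows[f"otu{j}"] = {
            "phylum": p,
            "class": f"{p}_c{j % 2}",
            "order": f"{p}_o{j % 3}",
            "family": f"{p}_f{j % 5}",
            "genus": f"{p}_g{j}",
        }
    return pd.DataFrame.from_dict(rows, orient="index")
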