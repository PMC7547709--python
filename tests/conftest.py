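import numpy as np
import pytest

from menanet.otu_io import OtuTable


def random_table(rng, n_samples=8, n_otus=12, high=60, with_taxonomy=False):
    counts = rng.integers(0, high, size=(n_samples, n_otus))
    # keep every sample and OTU non-empty
    counts[:, 0] += 1
    counts[0, :] += 1
    taxonomy = None
    if with_taxonomy:
        phyla = ["Proteobacteria", "Acidobacteria", "Actinobacteria"]
        taxonomy = {
            f"o{j}": f"d__Bacteria;p__{phyla[j % 3]}" for j in range(n_otus)
        }
    return OtuTable(
        [f"s{i:02d}" for i in range(n_samples)],
        [f"o{j}" for j in range(n_otus)],
        counts,
        taxonomy,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table(rng):
    return random_table(rng)
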