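import numpy as np
import pytest

from mdapred.synthetic import SyntheticSpec, generate, make_external_similarities


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """Planted 40-drug x 15-microbe dataset for fast end-to-end tests."""
    spec = SyntheticSpec(
        n_drugs=40, n_microbes=15, n_blocks=3,
        within_block_prob=0.5, background_prob=0.02, seed=11,
    )
    dataset, labels = generate(spec)
    return dataset, labels


@pytest.fixture(scope="session")
def small_similarities(small_dataset):
    _, labels = small_dataset
    return make_external_similarities(labels, reliability=0.9, seed=11)


@pytest.fixture
def pair_file(tmp_path):
    """Tiny association TSV with one duplicate pair."""
    path = tmp_path / "assoc.tsv"
    path.write_text("d1\tm1\nd1\tm2\nd2\tm2\nd1\tm1\n")
    return path
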