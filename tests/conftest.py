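import pytest

from tracevote.balloting import TraceConfig
from tracevote.fixtures import ToyDataset, make_toy_dataset


@pytest.fixture(scope="session")
def toy_dataset(tmp_path_factory) -> ToyDataset:
    """The 20-gene designed dataset used across the suite (seed 1)."""
    return make_toy_dataset(tmp_path_factory.mktemp("toy"), n_genes=20, seed=1)


@pytest.fixture()
def cfg() -> TraceConfig:
    return TraceConfig()
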