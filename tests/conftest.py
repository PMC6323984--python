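import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from plasmidnet.curate import curate
from plasmidnet.network import build_network
from plasmidnet.synthetic import generate_collection


@pytest.fixture(scope="session")
def collection():
    """Default synthetic plasmid collection (3 families + unrelated + decoys)."""
    return generate_collection(seed=11)


@pytest.fixture(scope="session")
def curated(collection):
    return curate(collection.records, set(collection.manifest.excluded))


@pytest.fixture(scope="session")
def graph(curated):
    return build_network(curated.kept)
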