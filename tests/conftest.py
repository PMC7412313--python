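import pytest

from graftmobile.simulate import (SimConfig, assign_truth, diverge,
                                  generate_ancestor, generate_rrna)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_transcripts=40, depth=15.0, master_seed=42)


@pytest.fixture(scope="session")
def small_references(small_config):
    ancestor = generate_ancestor(small_config)
    scion, rootstock = diverge(ancestor, small_config)
    return ancestor, scion, rootstock


@pytest.fixture(scope="session")
def small_truth(small_references, small_config):
    _, scion, _ = small_references
    regions = {
        ("full", "lowN", "lowP", "lowFe"): 5,
        ("full",): 2,
        ("lowN",): 3,
        ("lowP",): 2,
        ("lowFe",): 3,
        ("lowN", "lowFe"): 2,
    }
    return assign_truth(scion, regions, seed=small_config.master_seed)


@pytest.fixture(scope="session")
def rrna_refs():
    return generate_rrna(n=3, length=1200, seed=9)
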