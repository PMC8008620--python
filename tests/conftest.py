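import pytest

import chromarm as ca


@pytest.fixture(scope="session")
def small_specs():
    """Three two-armed chromosomes, desk-scale but arm-contrasted."""
    return [
        ca.ChromosomeSpec("chr1", 30_000, 60_000),
        ca.ChromosomeSpec("chr2", 35_000, 65_000),
        ca.ChromosomeSpec("chr3", 40_000, 70_000),
    ]


@pytest.fixture(scope="session")
def small_genome(small_specs):
    return ca.simulate_genome(small_specs, seed=11)
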