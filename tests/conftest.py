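import pytest

from mitochar.synth import SynthSpec, generate_genome, load_skeleton

GENOME_LENGTH = 16581

# printed spacing column of the packaged annotation, for rows 2..37 of the
# gene walk (row N's value = N.start - prev.stop - 1)
EXPECTED_INTERGENIC = [
    0, -1, -2, 0, 2, 0, -3, 1, 0, 0, 6, 1, 32, -1, 1, 3, 7, 0,
    0, 1, -43, -1, 0, 0, 0, 0, -7, 0, 0, 0, 0, -17, 0, 4, 0, -1,
]


@pytest.fixture(scope="session")
def skeleton():
    return load_skeleton(GENOME_LENGTH)


@pytest.fixture(scope="session")
def synth_genome():
    """One deterministic synthetic mitogenome plus its ground truth."""
    return generate_genome(SynthSpec(seed=1))
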