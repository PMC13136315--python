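import pytest

from photobarcode.codebook import Codebook, Codeword, build_codebook, default_alphabet


@pytest.fixture(scope="session")
def alphabet2():
    return default_alphabet(2)


@pytest.fixture(scope="session")
def alphabet4():
    return default_alphabet(4)


@pytest.fixture
def four_region_codebook():
    """Two letters, two rounds, regions I..IV = L1L1, L1L2, L2L1, L2L2."""
    return build_codebook(2, 2).assign(
        {"I": "L1L1", "II": "L1L2", "III": "L2L1", "IV": "L2L2"}
    )


@pytest.fixture
def mixed_species_codebook(alphabet4):
    """Two regions with doubly distinct codewords L1L3 / L2L4."""
    return Codebook(
        alphabet4,
        2,
        [Codeword((1, 3)), Codeword((2, 4))],
        {"top": Codeword((1, 3)), "bottom": Codeword((2, 4))},
    )
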