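import numpy as np
import pytest

from mdace import ArchitectureConfig, init_model
from mdace.sequence_data import ALPHABET, STANDARD_RESIDUES, encode_window


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_model():
    """A scaled-down network (fast to run, same code paths as the default)."""
    return init_model(ArchitectureConfig(input_channels=21, conv_channels=8,
                                         lstm_hidden=6, seed=7))


def random_window(rng, length=31, center_k=True):
    chars = [STANDARD_RESIDUES[i] for i in rng.integers(0, 20, size=length)]
    if center_k:
        chars[length // 2] = "K"
    return "".join(chars)


def random_batch(rng, n, length=31):
    """(n, length, 21) one-hot batch of random K-centred windows."""
    return np.stack([encode_window(random_window(rng, length)) for _ in range(n)])


@pytest.fixture
def fasta_file(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(">P1 first\nMKACDKLLKA\n>P2 second\nAAKAA\n")
    return path


@pytest.fixture
def sites_file(tmp_path):
    path = tmp_path / "sites.csv"
    path.write_text("protein_id,position\nP1,2\nP1,6\nP2,3\n")
    return path
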