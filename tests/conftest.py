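import numpy as np
import pytest

from proteogate import synthetic as syn
from proteogate.structure import parse_structure

PLANTED_PAIRS = [("GLU", "LYS", 3.0), ("ASP", "ARG", 3.5), ("GLU", "ARG", 3.9)]


@pytest.fixture(scope="session")
def toy_complex_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("structs") / "toy.pdb"
    path.write_text(syn.gen_toy_complex(PLANTED_PAIRS, decoys=6, seed=0))
    return path


@pytest.fixture(scope="session")
def toy_complex(toy_complex_path):
    return parse_structure(toy_complex_path, format="pdb")


@pytest.fixture(scope="session")
def pseudo_ring_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("structs") / "ring.pdb"
    path.write_text(syn.gen_pseudo_ring(7, 17.0, seed=0))
    return path


@pytest.fixture(scope="session")
def pseudo_ring(pseudo_ring_path):
    return parse_structure(pseudo_ring_path)
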