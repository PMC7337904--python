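"""Shared fixtures: synthetic duplexes and tiny hand-written PDB snippets."""
import tempfile

import numpy as np
import pytest
import hypothesis.configuration
from hypothesis import settings

# keep hypothesis' on-disk caches out of the repository
hypothesis.configuration.set_hypothesis_home_dir(
    tempfile.mkdtemp(prefix="hypothesis-"))

import ribograft as rg

# all property tests are derandomized; keep no on-disk example database
settings.register_profile("ribograft", database=None, derandomize=True,
                          deadline=None)
settings.load_profile("ribograft")

CRYSTAL_SEQ = "GTAGGACCATC"       # the 11-mer duplex with a single GGWCC site
LONG_SEQ = "GTAGGACCATCGTAGGACCATC"


@pytest.fixture(scope="session")
def duplex_a():
    model = rg.build_fiber_duplex(CRYSTAL_SEQ, "A")
    rg.assign_radii(model)
    return rg.pair_bases(model)


@pytest.fixture(scope="session")
def duplex_b():
    model = rg.build_fiber_duplex(CRYSTAL_SEQ, "B")
    rg.assign_radii(model)
    return rg.pair_bases(model)


@pytest.fixture(scope="session")
def long_duplex_a():
    model = rg.build_fiber_duplex(LONG_SEQ, "A")
    return rg.pair_bases(model)


@pytest.fixture(scope="session")
def long_duplex_b():
    model = rg.build_fiber_duplex(LONG_SEQ, "B")
    return rg.pair_bases(model)


@pytest.fixture()
def one_atom_pdb(tmp_path):
    text = (
        "CRYST1   37.100  116.200   56.800  90.00 102.90  90.00 P 1 21 1\n"
        "ATOM      1  CA  GLY A   1      11.104   6.134  -6.504  1.00 10.00"
        "           C\n"
        "END\n")
    path = tmp_path / "one_atom.pdb"
    path.write_text(text)
    return path


def random_rotation(rng):
    """Uniform proper rotation via QR of a Gaussian matrix."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
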