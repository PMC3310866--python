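import numpy as np
import pytest

from cdrdesign import confrot, pdm, synthfix
from cdrdesign.structio import assign_atom_types


@pytest.fixture(scope="session")
def rotamer_library():
    return confrot.default_rotamer_library()


@pytest.fixture(scope="session")
def toy_complex():
    """Two 4-residue strands facing across a 4 Å gap, with manifest."""
    return synthfix.make_toy_complex(seed=11, n_residues_a=4, n_residues_b=4,
                                     interface_gap=4.0)


@pytest.fixture(scope="session")
def separated_complex():
    """Chains more than 20 Å apart: no interface."""
    return synthfix.make_toy_complex(seed=12, n_residues_a=3, n_residues_b=3,
                                     interface_gap=30.0)


@pytest.fixture(scope="session")
def planted_stats():
    """Contact statistics from a library with a planted O_CARBONYL contact."""
    lib, manifest = synthfix.make_structure_library(
        seed=3, n_structures=4,
        planted_contact=("ALA", "O_CARBONYL", (3.0, 0.0, 0.0)))
    stats = pdm.collect_interior_contacts(lib, burial_cutoff=2.0)
    return stats, lib, manifest


@pytest.fixture(scope="session")
def water_stats():
    """Statistics with water oxygens planted 2.8 Å from the source residue."""
    lib, manifest = synthfix.make_structure_library(
        seed=7, n_structures=4,
        planted_contact=("ALA", "O_WATER", (2.8, 0.0, 0.0)))
    stats = pdm.collect_interior_contacts(lib, burial_cutoff=2.0)
    return stats, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def typed_toy_complex(toy_complex):
    s, manifest = toy_complex
    return assign_atom_types(s), manifest
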