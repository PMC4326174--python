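import numpy as np
import pytest

from allostery import Selection, build_toy
from allostery.structio import AtomRecord, Structure, Trajectory


@pytest.fixture(scope="session")
def toy():
    """Default synthetic system (seed 0), shared read-only across tests."""
    return build_toy(seed=0)


@pytest.fixture()
def tiny_structure():
    """Three hand-placed atoms across two residues and two chains."""
    atoms = [
        AtomRecord(1, "N", "GLY", "A", 10, np.array([0.0, 0.0, 0.0]), "N"),
        AtomRecord(2, "CA", "GLY", "A", 10, np.array([1.5, 0.0, 0.0]), "C"),
        AtomRecord(3, "CA", "ALA", "B", 11, np.array([0.0, 2.0, 1.0]), "C"),
    ]
    return Structure(atoms, label="tiny")


def make_structure(coords, resid_start=1, chain="A", resname="ALA"):
    """A structure with one CA atom per residue at the given coordinates."""
    coords = np.asarray(coords, dtype=float)
    atoms = [
        AtomRecord(i + 1, "CA", resname, chain, resid_start + i, c, "C")
        for i, c in enumerate(coords)
    ]
    return Structure(atoms)


def make_trajectory(structure, frames, times=None):
    return Trajectory(structure, frames, times)
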