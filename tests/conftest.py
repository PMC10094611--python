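"""Shared fixtures: synthetic toy systems built programmatically at test time."""

import numpy as np
import pytest

import fpchrom as fp
from fpchrom.structure_io import Atom, Structure


@pytest.fixture(scope="session")
def toy():
    """Default toy system: chromophore pocket with 19 shell residues."""
    spec = fp.GeneratorSpec(seed=1)
    structure, manifest = fp.make_toy_structure(spec)
    return structure, manifest


@pytest.fixture(scope="session")
def toy_chrom(toy):
    structure, _ = toy
    return fp.identify_chromophore(structure, "A")


def make_structure(atom_specs):
    """Build a Structure from (name, res_name, chain, res_seq, xyz[, hetero]) tuples."""
    atoms = []
    for k, spec in enumerate(atom_specs, start=1):
        name, res_name, chain, res_seq, xyz = spec[:5]
        hetero = spec[5] if len(spec) > 5 else False
        atoms.append(Atom(k, name, "", res_name, chain, res_seq, "",
                          np.asarray(xyz, float), hetero=hetero))
    return Structure(atoms=atoms)


@pytest.fixture
def two_ser_pair():
    """Two serine fragments with OG···OG at exactly 2.80 Å."""
    return make_structure([
        ("OG", "SER", "A", 1, (0.0, 0.0, 0.0)),
        ("CB", "SER", "A", 1, (-1.0, -0.8, 0.0)),
        ("OG", "SER", "A", 5, (2.80, 0.0, 0.0)),
        ("CB", "SER", "A", 5, (3.8, 0.8, 0.0)),
    ])


def hexagon(radius=1.39, z=0.0, center=(0.0, 0.0)):
    """Six ring-carbon positions of a regular hexagon."""
    ang = np.radians(np.arange(6) * 60.0)
    return np.column_stack((center[0] + radius * np.cos(ang),
                            center[1] + radius * np.sin(ang),
                            np.full(6, z)))
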