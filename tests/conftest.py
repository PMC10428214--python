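import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from trajnet.structures_io import Atom, Structure, Trajectory


def make_atom(serial=1, name="CA", resname="ALA", chain="A", resseq=1,
              element="C", coord=(0.0, 0.0, 0.0), **kw):
    return Atom(serial=serial, name=name, residue_name=resname, chain=chain,
                residue_seq=resseq, element=element, coord=tuple(coord), **kw)


def make_peptide(n_residues=3, resnames=None, spacing=3.8):
    """Minimal peptide: one CA + one CB per residue (CA only for GLY)."""
    resnames = resnames or ["ALA"] * n_residues
    atoms, serial = [], 1
    for i, rn in enumerate(resnames):
        x = i * spacing
        atoms.append(make_atom(serial, "CA", rn, "A", i + 1, "C", (x, 0, 0)))
        serial += 1
        if rn != "GLY":
            atoms.append(make_atom(serial, "CB", rn, "A", i + 1, "C",
                                   (x, 1.5, 0)))
            serial += 1
    return Structure(atoms)


def make_triplet_structure(d_coord, h_coord, a_coord):
    """One donor residue (N + H) and one acceptor residue (O)."""
    return Structure([
        make_atom(1, "N", "DON", "A", 1, "N", d_coord),
        make_atom(2, "H", "DON", "A", 1, "H", h_coord),
        make_atom(3, "O", "ACC", "A", 2, "O", a_coord),
    ])


def random_structure(n_atoms, rng, coord_scale=50.0):
    atoms = []
    for i in range(n_atoms):
        coord = tuple(np.round(rng.uniform(-coord_scale, coord_scale, 3), 3))
        atoms.append(make_atom(i + 1, "CB", "ALA", "A", i + 1, "C", coord))
    return Structure(atoms)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def peptide():
    return make_peptide(3)


def static_trajectory(structure, n_frames=5):
    coords = structure.coords
    return Trajectory(structure, np.repeat(coords[None], n_frames, axis=0))
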