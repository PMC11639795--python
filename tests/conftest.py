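import math

import numpy as np
import pytest

from pepforge import sasa, structure, synth
from pepforge.structure import Atom, Residue, ResidueKey, Structure


def make_atom(name="CA", element="C", coords=(0.0, 0.0, 0.0), radius=1.7,
              serial=1, **kw):
    a = Atom(serial=serial, name=name, element=element,
             coords=np.array(coords, dtype=float), **kw)
    a.vdw_radius = radius
    return a


def single_atom_structure(radius=1.7):
    res = Residue(ResidueKey("A", 1), "ALA", [make_atom(radius=radius)])
    return Structure([(1, {"A": [res]})])


def atoms_structure(specs):
    """specs: list of (coords, radius[, resseq]) -> one-chain structure with
    one CA atom per residue."""
    residues = []
    for i, spec in enumerate(specs):
        coords, radius = spec[0], spec[1]
        resseq = spec[2] if len(spec) > 2 else i + 1
        residues.append(Residue(ResidueKey("A", resseq), "ALA",
                                [make_atom(coords=coords, radius=radius,
                                           serial=i + 1)]))
    return Structure([(1, {"A": residues})])


def brute_force_sasa(coords, radii, probe=1.4, n_points=100_000, seed=1234):
    """Independent quadrature oracle: uniform random points on each expanded
    sphere, rejecting points inside any other expanded sphere."""
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float)
    expanded = np.asarray(radii, dtype=float) + probe
    areas = []
    for i in range(len(coords)):
        pts = rng.normal(size=(n_points, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts = coords[i] + expanded[i] * pts
        ok = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            ok &= np.sum((pts - coords[j]) ** 2, axis=1) > expanded[j] ** 2
        areas.append(ok.mean() * 4 * math.pi * expanded[i] ** 2)
    return np.array(areas)


@pytest.fixture(scope="session")
def toy_complex():
    return synth.make_toy_complex()


@pytest.fixture(scope="session")
def helix():
    return synth.make_helix(12)


@pytest.fixture(scope="session")
def sasa_fixture_structures():
    """Small structures exercised by the cross-algorithm checks."""
    dimer = atoms_structure([((0, 0, 0), 1.7), ((2.0, 0, 0), 1.7)])
    trimer = atoms_structure([((0, 0, 0), 1.7), ((2.2, 0, 0), 1.5),
                              ((4.2, 0, 0), 1.7)])
    single = single_atom_structure()
    helix = synth.make_helix(8)
    return {"single": single, "dimer": dimer, "trimer": trimer, "helix": helix}
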