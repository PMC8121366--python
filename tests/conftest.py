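import math

import numpy as np
import pytest

from lobescope import (
    Atom,
    Chain,
    HelixSpec,
    Residue,
    Structure,
    make_helix_dimer,
    make_ideal_helix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20211405)


@pytest.fixture
def ideal_helix():
    return make_ideal_helix(HelixSpec(n_res=20))


@pytest.fixture
def helix_dimer():
    return make_helix_dimer(HelixSpec(n_res=20), separation=9.0, cross_angle=140.7)


def single_atom_structure(element="C", coords=(0.0, 0.0, 0.0)):
    return Structure(
        chains=[
            Chain(
                id="A",
                residues=[
                    Residue(name="ALA", seq_id=1,
                            atoms=[Atom(name="X", element=element, coords=np.asarray(coords))])
                ],
            )
        ]
    )


def structure_from_atoms(chain_atoms):
    """Build a structure from {chain_id: [(resname, seq_id, atom_name, element, xyz), ...]}."""
    chains = []
    for cid, atoms in chain_atoms.items():
        residues = {}
        for resname, seq_id, atom_name, element, xyz in atoms:
            res = residues.setdefault(seq_id, Residue(name=resname, seq_id=seq_id))
            res.atoms.append(Atom(name=atom_name, element=element, coords=np.asarray(xyz, dtype=float)))
        chains.append(Chain(id=cid, residues=[residues[k] for k in sorted(residues)]))
    return Structure(chains=chains)


def random_rigid_transform(rng):
    """A random proper rotation + translation."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=20.0, size=3)
    return q, t


def apply_rigid(structure, rotation, translation):
    import dataclasses

    chains = []
    for chain in structure.chains:
        residues = [
            dataclasses.replace(
                res,
                atoms=[dataclasses.replace(a, coords=rotation @ a.coords + translation)
                       for a in res.atoms],
            )
            for res in chain.residues
        ]
        chains.append(Chain(id=chain.id, residues=residues, helices=list(chain.helices)))
    return Structure(chains=chains, source_id=structure.source_id)


def solid_sphere_cloud(rng, radius=15.0, n=4000):
    """Uniform point cloud in a ball, as a single-chain carbon structure."""
    pts = []
    while len(pts) < n:
        cand = rng.uniform(-radius, radius, size=(2 * n, 3))
        keep = cand[(cand**2).sum(axis=1) <= radius**2]
        pts.extend(keep.tolist())
    pts = np.asarray(pts[:n])
    residues = [
        Residue(name="ALA", seq_id=i + 1,
                atoms=[Atom(name="CA", element="C", coords=p)])
        for i, p in enumerate(pts)
    ]
    return Structure(chains=[Chain(id="A", residues=residues)])
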