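"""Solvent-accessible surface area, buried surface area, and interface contacts.

SASA is computed with the Shrake-Rupley numerical method: each heavy atom's
sphere is expanded by the probe radius (1.4 A water), sampled with a
deterministic Fibonacci lattice (960 points by default), and points occluded
by any neighbouring expanded sphere are discarded. The buried surface area of
a two-part complex is

    BSA_total = SASA(A alone) + SASA(B alone) - SASA(AB),

counting both faces of the interface; "interface area" is half of that, the
single-face figure interface servers usually print. Both are reported.

Contacts are classified by distance only (deposited crystal structures rarely
carry hydrogens): inter-part N/O pairs within 3.5 A are hydrogen bonds unless
the pair belongs to the charged-group sets (Lys NZ, Arg NE/NH1/NH2,
His ND1/NE2 versus Asp OD1/OD2, Glu OE1/OE2) within 4.0 A, which are salt
bridges; carbon-carbon pairs within 4.0 A count as nonpolar contacts.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .structio import Structure

__all__ = [
    "RadiiSet",
    "ContactCriteria",
    "Contact",
    "InterfaceReport",
    "fibonacci_sphere",
    "sasa",
    "buried_surface_area",
    "classify_interface_contacts",
    "interface_report",
]

#: van der Waals radii (A) for heavy elements, common Shrake-Rupley choice.
DEFAULT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "SE": 1.90, "P": 1.80}


@dataclasses.dataclass
class RadiiSet:
    radii: dict[str, float] = dataclasses.field(default_factory=lambda: dict(DEFAULT_RADII))
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    default_radius: float = 1.80  # used (with a warning) for unknown elements

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()) or self.default_radius <= 0:
            raise ValueError("van der Waals radii must be positive")
        if self.n_sphere_points < 92:
            raise ValueError("n_sphere_points must be >= 92")

    def radius_of(self, element: str) -> float:
        el = element.upper()
        if el in self.radii:
            return self.radii[el]
        warnings.warn(f"element {element!r} not in radii table; using {self.default_radius} A")
        return self.default_radius


@dataclasses.dataclass
class ContactCriteria:
    hbond_da_max: float = 3.5
    saltbridge_max: float = 4.0
    nonpolar_max: float = 4.0

    def __post_init__(self) -> None:
        if min(self.hbond_da_max, self.saltbridge_max, self.nonpolar_max) <= 0:
            raise ValueError("contact cutoffs must be positive")


@dataclasses.dataclass(frozen=True)
class Contact:
    """One inter-part atom pair, identified by (chain, seq_id, residue, atom)."""

    atom_a: tuple[str, int, str, str]
    atom_b: tuple[str, int, str, str]
    distance: float


@dataclasses.dataclass
class InterfaceReport:
    bsa_total: float = 0.0
    interface_area: float = 0.0
    hbonds: list[Contact] = dataclasses.field(default_factory=list)
    saltbridges: list[Contact] = dataclasses.field(default_factory=list)
    nonpolar_contacts: int = 0
    interface_residues: dict[str, list[tuple[str, int, str]]] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        def _c(c: Contact) -> dict:
            return {"atom_a": list(c.atom_a), "atom_b": list(c.atom_b),
                    "distance": round(c.distance, 3)}

        return {
            "bsa_total_A2": round(self.bsa_total, 1),
            "interface_area_A2": round(self.interface_area, 1),
            "n_hbonds": len(self.hbonds),
            "n_saltbridges": len(self.saltbridges),
            "n_nonpolar_contacts": self.nonpolar_contacts,
            "hbonds": [_c(c) for c in self.hbonds],
            "saltbridges": [_c(c) for c in self.saltbridges],
            "interface_residues": {
                part: [list(r) for r in residues]
                for part, residues in self.interface_residues.items()
            },
        }


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform n-point lattice on the unit sphere."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * math.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _heavy_atoms(structure: Structure):
    atoms = list(structure.iter_atoms(include_hydrogens=False))
    if not atoms:
        raise ValueError("structure contains no heavy atoms")
    return atoms


def sasa(structure: Structure, params: RadiiSet | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2) over heavy atoms.

    The atom order matches ``structure.iter_atoms(include_hydrogens=False)``.
    """
    params = params or RadiiSet()
    atoms = _heavy_atoms(structure)
    coords = np.asarray([a.coords for _, _, a in atoms])
    radii = np.asarray([params.radius_of(a.element) + params.probe_radius for _, _, a in atoms])
    sphere = fibonacci_sphere(params.n_sphere_points)

    tree = cKDTree(coords)
    max_reach = 2.0 * radii.max()
    areas = np.zeros(len(atoms))
    point_area = 4.0 * math.pi / params.n_sphere_points
    for i in range(len(atoms)):
        neighbours = [j for j in tree.query_ball_point(coords[i], radii[i] + radii.max())
                      if j != i and np.linalg.norm(coords[j] - coords[i]) < radii[i] + radii[j]]
        pts = coords[i] + radii[i] * sphere
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbours:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        areas[i] = accessible.sum() * point_area * radii[i] ** 2
    return areas


def _per_residue_sasa(structure: Structure, params: RadiiSet) -> dict[tuple[str, int, str], float]:
    atoms = _heavy_atoms(structure)
    areas = sasa(structure, params)
    out: dict[tuple[str, int, str], float] = {}
    for (chain, res, _), area in zip(atoms, areas):
        key = (chain.id, res.seq_id, res.insertion_code)
        out[key] = out.get(key, 0.0) + area
    return out


def _split_parts(complex_structure: Structure, part_a: Iterable[str], part_b: Iterable[str]):
    set_a, set_b = set(part_a), set(part_b)
    if not set_a or not set_b:
        raise ValueError("both parts must name at least one chain")
    if set_a & set_b:
        raise ValueError(f"parts overlap on chains {sorted(set_a & set_b)}")
    have = {c.id for c in complex_structure.chains}
    missing = (set_a | set_b) - have
    if missing:
        raise ValueError(f"chains {sorted(missing)} not present in complex (have {sorted(have)})")
    return complex_structure.subset(sorted(set_a)), complex_structure.subset(sorted(set_b))


def buried_surface_area(
    complex_structure: Structure,
    part_a: Iterable[str],
    part_b: Iterable[str],
    params: RadiiSet | None = None,
    delta_tolerance: float = 0.1,
) -> InterfaceReport:
    """Buried surface area of the A|B interface and the residues forming it.

    Interface residues are those losing more than ``delta_tolerance`` (A^2) of
    SASA upon complexation.
    """
    params = params or RadiiSet()
    sub_a, sub_b = _split_parts(complex_structure, part_a, part_b)
    both = complex_structure.subset(sorted({c.id for c in sub_a.chains} | {c.id for c in sub_b.chains}))

    free = _per_residue_sasa(sub_a, params)
    free.update(_per_residue_sasa(sub_b, params))
    bound = _per_residue_sasa(both, params)

    bsa = sum(free.values()) - sum(bound.values())
    a_ids = {c.id for c in sub_a.chains}
    residues: dict[str, list] = {"part_a": [], "part_b": []}
    for key in sorted(free):
        if free[key] - bound.get(key, 0.0) > delta_tolerance:
            residues["part_a" if key[0] in a_ids else "part_b"].append(key)
    return InterfaceReport(
        bsa_total=max(bsa, 0.0) if abs(bsa) < 1.0 else bsa,
        interface_area=(max(bsa, 0.0) if abs(bsa) < 1.0 else bsa) / 2.0,
        interface_residues=residues,
    )


# charged-group atom names for salt-bridge detection
_BASIC = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
          ("HIS", "ND1"), ("HIS", "NE2")}
_ACIDIC = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


def _atom_key(chain, res, atom) -> tuple[str, int, str, str]:
    return (chain.id, res.seq_id, res.name, atom.name)


def classify_interface_contacts(
    complex_structure: Structure,
    part_a: Iterable[str],
    part_b: Iterable[str],
    criteria: ContactCriteria | None = None,
) -> InterfaceReport:
    """Classify inter-part atom pairs into salt bridges, H-bonds and nonpolar contacts.

    Salt bridges take precedence: a charged-group N/O pair within the salt
    bridge cutoff is never double-counted as a hydrogen bond. Output lists are
    deterministically ordered by (chain, seq_id, atom name).
    """
    criteria = criteria or ContactCriteria()
    sub_a, sub_b = _split_parts(complex_structure, part_a, part_b)
    atoms_a = [(c, r, a) for c, r, a in sub_a.iter_atoms(include_hydrogens=False)]
    atoms_b = [(c, r, a) for c, r, a in sub_b.iter_atoms(include_hydrogens=False)]
    xa = np.asarray([a.coords for _, _, a in atoms_a])
    xb = np.asarray([a.coords for _, _, a in atoms_b])
    tree_b = cKDTree(xb)
    cutoff = max(criteria.hbond_da_max, criteria.saltbridge_max, criteria.nonpolar_max)

    hbonds, saltbridges = [], []
    n_nonpolar = 0
    for i, (ca, ra, aa) in enumerate(atoms_a):
        for j in sorted(tree_b.query_ball_point(xa[i], cutoff)):
            cb, rb, ab = atoms_b[j]
            d = float(np.linalg.norm(xa[i] - xb[j]))
            ela, elb = aa.element.upper(), ab.element.upper()
            if ela == "C" and elb == "C":
                if d <= criteria.nonpolar_max:
                    n_nonpolar += 1
                continue
            if ela in ("N", "O") and elb in ("N", "O"):
                pa, pb = (ra.name, aa.name), (rb.name, ab.name)
                is_salt = (
                    (pa in _BASIC and pb in _ACIDIC) or (pa in _ACIDIC and pb in _BASIC)
                ) and d <= criteria.saltbridge_max
                contact = Contact(_atom_key(ca, ra, aa), _atom_key(cb, rb, ab), d)
                if is_salt:
                    saltbridges.append(contact)
                elif d <= criteria.hbond_da_max:
                    hbonds.append(contact)

    order = lambda c: (c.atom_a[0], c.atom_a[1], c.atom_a[3], c.atom_b[0], c.atom_b[1], c.atom_b[3])
    return InterfaceReport(
        hbonds=sorted(hbonds, key=order),
        saltbridges=sorted(saltbridges, key=order),
        nonpolar_contacts=n_nonpolar,
    )


def interface_report(
    complex_structure: Structure,
    part_a: Iterable[str],
    part_b: Iterable[str],
    params: RadiiSet | None = None,
    criteria: ContactCriteria | None = None,
) -> InterfaceReport:
    """Full interface report: areas, interface residues, and contact lists."""
    areas = buried_surface_area(complex_structure, part_a, part_b, params)
    contacts = classify_interface_contacts(complex_structure, part_a, part_b, criteria)
    areas.hbonds = contacts.hbonds
    areas.saltbridges = contacts.saltbridges
    areas.nonpolar_contacts = contacts.nonpolar_contacts
    return areas
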