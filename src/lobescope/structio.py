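"""Structure and alignment I/O.

A thin hierarchical model (chains -> residues -> atoms) backed by gemmi for
parsing and writing PDB/mmCIF. Coordinates stay in Angstrom and author
numbering throughout; nothing is renumbered, because downstream reports refer
to author residue numbers (e.g. Ser79).

Alternate locations are resolved at read time: for each (residue, atom name)
the highest-occupancy conformer is kept, ties broken by the lexicographically
first altloc identifier. Hydrogens are retained in the model but excluded by
default from SASA and RMSD calculations.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "MSA",
    "StructureFormatError",
    "EmptyStructureError",
    "AlignmentWidthError",
    "read_structure",
    "write_structure",
    "write_structure_with_scores",
    "build_assembly",
    "read_msa",
    "write_msa",
    "three_to_one",
]

#: One-letter codes for the 20 standard residues plus common variants.
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

_KNOWN_ELEMENTS = {"H", "C", "N", "O", "S", "P", "SE", "FE", "ZN", "MG", "CA", "MN", "NA", "K", "CL", "I"}


class StructureFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a parsed file contains no atoms."""


class AlignmentWidthError(ValueError):
    """Raised when an aligned FASTA has rows of unequal length."""


def three_to_one(name: str) -> str:
    """One-letter code for a 3-letter residue name ('X' if unknown)."""
    return _THREE_TO_ONE.get(name.upper(), "X")


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    bfactor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def element_known(self) -> bool:
        return self.element.upper() in _KNOWN_ELEMENTS


@dataclasses.dataclass
class Residue:
    name: str
    seq_id: int
    insertion_code: str = ""
    atoms: list[Atom] = dataclasses.field(default_factory=list)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return three_to_one(self.name)


@dataclasses.dataclass
class Chain:
    id: str
    residues: list[Residue] = dataclasses.field(default_factory=list)
    #: (start_seq_id, end_seq_id) ranges from HELIX/annotation records
    helices: list[tuple[int, int]] = dataclasses.field(default_factory=list)

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclasses.dataclass
class Structure:
    chains: list[Chain] = dataclasses.field(default_factory=list)
    #: (rotation 3x3, translation 3-vector) operators from BIOMT/assembly records
    assembly_ops: list[tuple[np.ndarray, np.ndarray]] = dataclasses.field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids: {ids}")
        for rot, _ in self.assembly_ops:
            if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-6):
                raise ValueError("assembly rotation block is not orthonormal")

    def get_chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}; have {[c.id for c in self.chains]}")

    def iter_atoms(self, include_hydrogens: bool = True) -> Iterator[tuple[Chain, Residue, Atom]]:
        for chain in self.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    if not include_hydrogens and atom.is_hydrogen:
                        continue
                    yield chain, res, atom

    def coordinates(self, include_hydrogens: bool = True) -> np.ndarray:
        pts = [a.coords for _, _, a in self.iter_atoms(include_hydrogens)]
        if not pts:
            return np.empty((0, 3))
        return np.asarray(pts)

    def subset(self, chain_ids: Iterable[str]) -> "Structure":
        wanted = list(chain_ids)
        chains = [self.get_chain(cid) for cid in wanted]
        return Structure(chains=chains, assembly_ops=[], source_id=self.source_id)


@dataclasses.dataclass
class MSA:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence identifiers are not unique")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise AlignmentWidthError(f"rows have differing lengths: {sorted(widths)}")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"no sequence {seq_id!r} in MSA") from None


# ---------------------------------------------------------------------------
# reading


def _resolve_altlocs(raw_atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, tie -> first altloc."""
    by_name: dict[str, Atom] = {}
    order: list[str] = []
    for atom in raw_atoms:
        if atom.name not in by_name:
            by_name[atom.name] = atom
            order.append(atom.name)
        else:
            cur = by_name[atom.name]
            if (atom.occupancy, _altloc_key(atom.altloc)) > (cur.occupancy, _altloc_key(cur.altloc)):
                by_name[atom.name] = atom
    return [by_name[n] for n in order]


def _altloc_key(altloc: str) -> tuple[int, str]:
    # reversed lexicographic preference: '' or 'A' beats 'B' on occupancy tie
    return (0, "") if not altloc else (-ord(altloc[0]), altloc)


def _from_gemmi(st: gemmi.Structure, source_id: str) -> Structure:
    if len(st) == 0:
        raise EmptyStructureError(f"{source_id}: no models in file")
    model = st[0]  # first model only (no NMR multi-model averaging)

    helices_by_chain: dict[str, list[tuple[int, int]]] = {}
    for helix in st.helices:
        cname = helix.start.chain_name
        helices_by_chain.setdefault(cname, []).append(
            (helix.start.res_id.seqid.num, helix.end.res_id.seqid.num)
        )

    ops: list[tuple[np.ndarray, np.ndarray]] = []
    for assembly in st.assemblies:
        for gen in assembly.generators:
            for oper in gen.operators:
                tr = oper.transform
                rot = np.array(tr.mat.tolist(), dtype=float)
                vec = np.array(tr.vec.tolist(), dtype=float)
                ops.append((rot, vec))
        break  # first (deposited "author_and_software_defined") assembly only

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            raw = [
                Atom(
                    name=ga.name,
                    element=ga.element.name.upper(),
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    bfactor=ga.b_iso,
                    altloc=ga.altloc if ga.altloc != "\0" else "",
                )
                for ga in gres
            ]
            residues.append(
                Residue(
                    name=gres.name,
                    seq_id=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    atoms=_resolve_altlocs(raw),
                )
            )
        chains.append(Chain(id=gchain.name, residues=residues,
                            helices=helices_by_chain.get(gchain.name, [])))

    out = Structure(chains=chains, assembly_ops=ops, source_id=source_id)
    if not any(True for _ in out.iter_atoms()):
        raise EmptyStructureError(f"{source_id}: model contains no atoms")
    return out


def read_structure(path: str | Path, dialect: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into the hierarchical model.

    ``dialect`` is one of ``pdb``, ``mmcif`` or ``auto`` (extension sniffing).
    The first model is used; altlocs are collapsed to the highest-occupancy
    conformer; HELIX records and assembly (BIOMT) operators are captured.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if dialect == "pdb":
            st = gemmi.read_pdb(str(path))
        elif dialect == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        elif dialect == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown dialect {dialect!r}; use pdb, mmcif or auto")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "dialect" in str(exc):
            raise
        raise StructureFormatError(f"{path}: {exc}") from exc
    st.setup_entities()
    return _from_gemmi(st, source_id=path.stem)


# ---------------------------------------------------------------------------
# writing


def _to_gemmi(structure: Structure, bfactors: Mapping[tuple[str, int, str], float] | None = None) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.source_id or "lobescope"
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element.capitalize())
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                if bfactors is not None:
                    key = (chain.id, res.seq_id, res.insertion_code)
                    ga.b_iso = bfactors.get(key, 0.0)
                else:
                    ga.b_iso = atom.bfactor
                ga.altloc = atom.altloc or "\0"
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    for chain in structure.chains:
        by_seqid = {r.seq_id: r for r in chain.residues}
        for start, end in chain.helices:
            helix = gemmi.Helix()
            for attr, seq_id in (("start", start), ("end", end)):
                res = by_seqid.get(seq_id)
                addr = gemmi.AtomAddress()
                addr.chain_name = chain.id
                addr.res_id.seqid = gemmi.SeqId(seq_id, " ")
                addr.res_id.name = res.name if res else "ALA"
                setattr(helix, attr, addr)
            helix.length = end - start + 1
            st.helices.append(helix)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write the structure as PDB (coordinates to the format's 1e-3 A precision)."""
    _to_gemmi(structure).write_pdb(str(path))


def write_structure_with_scores(
    structure: Structure,
    scores: Mapping[tuple[str, int, str] | tuple[str, int], float],
    path: str | Path,
    sentinel: float = 0.0,
) -> None:
    """Write a PDB whose B-factor column carries a per-residue score.

    ``scores`` maps ``(chain_id, seq_id)`` or ``(chain_id, seq_id, icode)`` to a
    real value; every atom of the residue gets the value, clamped to
    [0, 999.99] (the column's printable range). Unscored residues get
    ``sentinel``. Used for e.g. painting conservation onto a dimer.
    """
    norm: dict[tuple[str, int, str], float] = {}
    for key, value in scores.items():
        if len(key) == 2:
            key = (key[0], key[1], "")
        norm[tuple(key)] = float(min(max(value, 0.0), 999.99))
    present = {(c.id, r.seq_id, r.insertion_code) for c in structure.chains for r in c.residues}
    missing = set(norm) - present
    if missing:
        raise KeyError(f"scores refer to residues absent from structure: {sorted(missing)[:5]}")
    full = {k: norm.get(k, sentinel) for k in present}
    _to_gemmi(structure, bfactors=full).write_pdb(str(path))


# ---------------------------------------------------------------------------
# assemblies


def build_assembly(structure: Structure, op_indices: Sequence[int] | str = "all") -> Structure:
    """Apply deposited assembly operators, producing the expanded assembly.

    Each requested operator maps every chain to an image chain named
    ``<original id><operator index>`` (deterministic, so interface reports are
    reproducible). Operator indices are 0-based positions in
    ``structure.assembly_ops``.
    """
    ops = structure.assembly_ops
    if op_indices == "all":
        indices = list(range(len(ops)))
    else:
        indices = list(op_indices)
    if not ops:
        raise ValueError("structure carries no assembly operators")
    bad = [i for i in indices if not 0 <= i < len(ops)]
    if bad:
        raise ValueError(f"operators {bad} not available; have indices 0..{len(ops) - 1}")

    chains: list[Chain] = []
    for idx in indices:
        rot, vec = ops[idx]
        for chain in structure.chains:
            new_res = []
            for res in chain.residues:
                new_atoms = [
                    dataclasses.replace(a, coords=rot @ a.coords + vec)
                    for a in res.atoms
                ]
                new_res.append(dataclasses.replace(res, atoms=new_atoms))
            chains.append(Chain(id=f"{chain.id}{idx}", residues=new_res, helices=list(chain.helices)))
    return Structure(chains=chains, assembly_ops=[], source_id=structure.source_id)


# ---------------------------------------------------------------------------
# MSAs


def read_msa(path: str | Path) -> MSA:
    """Read an aligned FASTA. Rows are uppercased and '.' gaps become '-'."""
    from Bio import SeqIO

    ids: list[str] = []
    rows: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        rows.append(str(record.seq).upper().replace(".", "-"))
    if not ids:
        raise AlignmentWidthError(f"{path}: no FASTA records found")
    width = len(rows[0])
    for rid, row in zip(ids, rows):
        if len(row) != width:
            raise AlignmentWidthError(
                f"{path}: record {rid!r} has length {len(row)}, expected {width}"
            )
    return MSA(ids=ids, rows=rows)


def write_msa(msa: MSA, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")
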