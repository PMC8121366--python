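"""Seeded generators for every input class the pipeline consumes.

These produce idealized stand-ins for the real inputs - Cα-trace α-helices
and two-helix dimers for geometry and interface work, alignments with
controlled per-column entropy / gap content / redundancy structure for the
conservation pipeline, and noisy Debye curves for the scattering utilities -
each carrying its ground truth so recovery tests can score the estimators.

All generators take an explicit seed (no global random state) and are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .saxs import ScatteringCurve, debye_intensity
from .structio import Atom, Chain, Residue, Structure
from .conservation import AMINO_ACIDS

__all__ = [
    "HelixSpec",
    "make_ideal_helix",
    "make_helix_dimer",
    "make_synthetic_msa",
    "make_synthetic_curve",
    "SyntheticMSA",
]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclasses.dataclass
class HelixSpec:
    """Ideal α-helix parameters: 1.5 A rise and 100 deg twist per residue,
    Cα cylinder radius 2.3 A (textbook values)."""

    n_res: int = 20
    rise: float = 1.5
    twist: float = 100.0
    ca_radius: float = 2.3
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.n_res < 5:
            raise ValueError("helix needs at least 5 residues")
        if self.rise <= 0 or self.ca_radius <= 0:
            raise ValueError("rise and ca_radius must be positive")
        if self.sequence is not None and len(self.sequence) != self.n_res:
            raise ValueError("sequence length must equal n_res")


def _helix_chain(spec: HelixSpec, chain_id: str) -> Chain:
    residues = []
    for i in range(spec.n_res):
        theta = math.radians(spec.twist) * i
        ca = np.array([
            spec.ca_radius * math.cos(theta),
            spec.ca_radius * math.sin(theta),
            spec.rise * i,
        ])
        one = spec.sequence[i] if spec.sequence else "A"
        residues.append(
            Residue(
                name=_ONE_TO_THREE.get(one.upper(), "ALA"),
                seq_id=i + 1,
                atoms=[Atom(name="CA", element="C", coords=ca)],
            )
        )
    return Chain(id=chain_id, residues=residues, helices=[(1, spec.n_res)])


def make_ideal_helix(spec: HelixSpec | None = None, chain_id: str = "A") -> Structure:
    """Cα-trace ideal helix along +z, residue i at angle i*twist, height i*rise."""
    spec = spec or HelixSpec()
    st = Structure(chains=[_helix_chain(spec, chain_id)], source_id="ideal-helix")
    st.metadata = {"spec": spec}
    return st


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + math.sin(a) * k + (1 - math.cos(a)) * (k @ k)


def make_helix_dimer(
    spec: HelixSpec | None = None,
    separation: float = 9.0,
    cross_angle: float = 140.7,
) -> Structure:
    """Two-chain helix dimer with a prescribed axis separation and crossing angle.

    Chain A runs along +z centered at the origin; chain B is chain A rotated
    by ``cross_angle`` about the inter-axis normal (x) and shifted by
    ``separation`` along it, so the ground-truth crossing angle between the
    N->C axes equals ``cross_angle``. Ground truth is kept in ``.metadata``.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    spec = spec or HelixSpec()
    chain_a = _helix_chain(spec, "A")
    # center on the helix axis midpoint
    z_shift = spec.rise * (spec.n_res - 1) / 2.0
    for res in chain_a.residues:
        res.atoms[0].coords = res.atoms[0].coords - np.array([0.0, 0.0, z_shift])

    rot = _rotation_about(np.array([1.0, 0.0, 0.0]), cross_angle)
    offset = np.array([separation, 0.0, 0.0])
    chain_b = Chain(
        id="B",
        residues=[
            Residue(
                name=res.name,
                seq_id=res.seq_id,
                atoms=[Atom(name="CA", element="C", coords=rot @ res.atoms[0].coords + offset)],
            )
            for res in chain_a.residues
        ],
        helices=[(1, spec.n_res)],
    )
    st = Structure(chains=[chain_a, chain_b], source_id="helix-dimer")
    st.metadata = {"spec": spec, "separation": separation, "cross_angle": cross_angle}
    return st


@dataclasses.dataclass
class SyntheticMSA:
    """An alignment plus the ground truth it was generated from."""

    ids: list[str]
    rows: list[str]
    target_entropy: np.ndarray
    cluster_of: list[int]  # redundancy cluster index per row

    def to_msa(self):
        from .structio import MSA

        return MSA(ids=list(self.ids), rows=list(self.rows))


def _mixture_for_entropy(target_s: float) -> np.ndarray:
    """Residue-type probabilities whose log20 entropy equals ``target_s``.

    Uses the smallest residue-type count that can reach the target: k types
    uniformly give S = log20(k), so for log20(k) <= S < log20(k+1) the column
    is k types at (1-q)/k plus one extra type at q, with q in [0, 1/(k+1)]
    found by bisection. S = 0 is a single type; S = 1 all twenty, uniform.
    """
    if not 0.0 <= target_s <= 1.0:
        raise ValueError("per-column target entropy must lie in [0, 1]")
    if target_s == 0.0:
        return np.array([1.0])
    ln20 = math.log(20.0)
    k = int(math.floor(math.exp(target_s * ln20)))
    if k >= 20:
        return np.full(20, 0.05)

    def entropy(q: float) -> float:
        probs = np.concatenate([np.full(k, (1.0 - q) / k), [q]])
        nz = probs[probs > 0]
        return float(-(nz * np.log(nz)).sum() / ln20)

    lo, hi = 0.0, 1.0 / (k + 1)  # entropy grows from log20(k) to log20(k+1)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if entropy(mid) < target_s:
            lo = mid
        else:
            hi = mid
    q = 0.5 * (lo + hi)
    return np.concatenate([np.full(k, (1.0 - q) / k), [q]])


def make_synthetic_msa(
    n_seq: int,
    length: int,
    conservation_profile,
    gap_profile=None,
    redundancy: tuple[int, int] | None = None,
    seed: int | None = None,
) -> SyntheticMSA:
    """Alignment with per-column target entropies, gaps, and redundancy clusters.

    Each column draws from a small residue mixture parameterized to hit the
    target entropy in expectation (two residue types suffice for targets up to
    log20(2) ~ 0.231; higher targets use more types). Without ``redundancy``
    the rows are sampled
    independently. With ``redundancy=(n_clusters, mutations_per_copy)`` the
    rows are near-copies of per-cluster founder sequences, each copy carrying
    the stated number of point mutations - emulating the redundant hit lists
    a database search returns before pruning.
    """
    if seed is None:
        raise ValueError("a seed is required")
    profile = np.asarray(conservation_profile, dtype=float)
    if profile.shape != (length,):
        raise ValueError("conservation_profile length must equal alignment length")
    gaps = np.zeros(length) if gap_profile is None else np.asarray(gap_profile, dtype=float)
    if gaps.shape != (length,) or np.any((gaps < 0) | (gaps >= 1)):
        raise ValueError("gap_profile must be per-column fractions in [0, 1)")
    rng = np.random.default_rng(seed)

    aa = np.array(list(AMINO_ACIDS))
    col_probs = [_mixture_for_entropy(s) for s in profile]
    col_types = [rng.choice(20, size=len(p), replace=False) for p in col_probs]

    def sample_row() -> np.ndarray:
        row = np.empty(length, dtype="U1")
        for c in range(length):
            row[c] = aa[col_types[c][rng.choice(len(col_probs[c]), p=col_probs[c])]]
        return row

    rows_arr: list[np.ndarray] = []
    cluster_of: list[int] = []
    if redundancy is None:
        for _ in range(n_seq):
            rows_arr.append(sample_row())
            cluster_of.append(len(rows_arr) - 1)
    else:
        n_clusters, n_mut = redundancy
        if not 1 <= n_clusters <= n_seq:
            raise ValueError("n_clusters must be in [1, n_seq]")
        founders = [sample_row() for _ in range(n_clusters)]
        for k in range(n_seq):
            cluster = k % n_clusters
            row = founders[cluster].copy()
            for pos in rng.choice(length, size=min(n_mut, length), replace=False):
                row[pos] = aa[rng.integers(20)]
            rows_arr.append(row)
            cluster_of.append(cluster)

    for row in rows_arr:
        gap_mask = rng.random(length) < gaps
        row[gap_mask] = "-"

    ids = [f"seq{i:04d}" for i in range(n_seq)]
    return SyntheticMSA(
        ids=ids,
        rows=["".join(r) for r in rows_arr],
        target_entropy=profile,
        cluster_of=cluster_of,
    )


def make_synthetic_curve(
    structure: Structure,
    q_grid=None,
    noise_frac: float = 0.01,
    seed: int | None = None,
    granularity: str = "atom",
) -> ScatteringCurve:
    """Noisy Debye curve of a structure: I -> I * (1 + noise), sigma = noise_frac * I."""
    if seed is None:
        raise ValueError("a seed is required")
    if q_grid is None:
        q_grid = np.linspace(0.0, 0.5, 201)
    ideal = debye_intensity(structure, q_grid, granularity=granularity)
    rng = np.random.default_rng(seed)
    noisy = ideal.intensity * (1.0 + noise_frac * rng.standard_normal(len(ideal.q)))
    return ScatteringCurve(
        q=ideal.q,
        intensity=np.clip(noisy, 0.0, None),
        sigma=noise_frac * ideal.intensity,
    )
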