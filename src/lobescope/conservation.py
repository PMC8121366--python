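"""Sequence variability pipeline: pairwise distances, redundancy pruning,
log20 column entropy, residue frequencies, and mapping onto structures.

Per-column variability is the Shannon entropy in base 20,

    S = - sum_{i=1..20} p_i log20 p_i,

where p_i are the frequencies of the 20 standard amino acids at the column
(gaps and ambiguity codes excluded, frequencies renormalized). With this base
S lies in [0, 1]: 0 for a fully conserved column, 1 when all 20 residues are
equally frequent. Higher S = more variable.

Redundancy pruning iterates pairs of sequences in ascending distance order
and removes one member of each still-intact pair until the target number of
sequences remains; removing the member with the smaller mean distance to the
other survivors keeps outliers, giving the most even spread of sequences.
Distances are p-distances (1 - fraction identical over mutually ungapped
columns) computed on the supplied alignment.

Homologue retrieval is out of scope; the e-value thresholds used to assemble
typical input sets are shipped as documented constants only.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .structio import MSA, Chain, Structure, write_structure_with_scores

__all__ = [
    "AMINO_ACIDS",
    "DistanceMatrix",
    "ColumnRecord",
    "EntropyProfile",
    "distance_matrix",
    "prune_redundancy",
    "column_entropy",
    "residue_frequencies",
    "map_entropy_to_structure",
    "BLAST_EVALUE_MAX",
    "PSIBLAST_STAGED_EVALUES",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: retrieval thresholds typical input sets were built with (documentation only)
BLAST_EVALUE_MAX = 1e-10
PSIBLAST_STAGED_EVALUES = (1e-20, 1e-10, 1e-8)


@dataclasses.dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match id count")


@dataclasses.dataclass
class ColumnRecord:
    frequencies: np.ndarray  # 20-vector over AMINO_ACIDS order
    gap_fraction: float
    n_effective: int  # number of standard residues the frequencies are based on
    entropy: float  # S in [0, 1]; nan when the column has no standard residue
    gap_flagged: bool = False


@dataclasses.dataclass
class EntropyProfile:
    columns: list[ColumnRecord]

    @property
    def entropies(self) -> np.ndarray:
        return np.asarray([c.entropy for c in self.columns])

    def to_rows(self, top_n: int = 3) -> list[dict]:
        """Flat records (column, gap_fraction, S, top residues) for TSV export."""
        rows = []
        for i, col in enumerate(self.columns, start=1):
            order = np.argsort(-col.frequencies)[:top_n]
            top = ",".join(
                f"{AMINO_ACIDS[j]}:{col.frequencies[j]:.2f}" for j in order if col.frequencies[j] > 0
            )
            rows.append(
                {
                    "column": i,
                    "gap_fraction": round(col.gap_fraction, 4),
                    "S": None if math.isnan(col.entropy) else round(col.entropy, 4),
                    "gap_flagged": col.gap_flagged,
                    "top_residues": top,
                }
            )
        return rows


def _row_matrix(msa: MSA) -> np.ndarray:
    return np.array([list(r) for r in msa.rows], dtype="U1")


def distance_matrix(msa: MSA) -> DistanceMatrix:
    """p-distance matrix of an alignment.

    Pairs with zero mutually ungapped columns get distance 1.0 with a warning.
    """
    if msa.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    rows = _row_matrix(msa)
    non_gap = rows != "-"
    n = msa.n_sequences
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = non_gap[i] & non_gap[j]
            n_comp = int(both.sum())
            if n_comp == 0:
                warnings.warn(
                    f"sequences {msa.ids[i]!r} and {msa.ids[j]!r} share no ungapped columns; "
                    "distance set to 1.0"
                )
                dist = 1.0
            else:
                dist = 1.0 - float((rows[i][both] == rows[j][both]).sum()) / n_comp
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids=list(msa.ids), d=d)


def prune_redundancy(msa: MSA, target_n: int, dm: DistanceMatrix | None = None) -> MSA:
    """Greedy redundancy removal down to ``target_n`` sequences.

    Pairs are visited in ascending distance (ties by lexicographic id pair);
    whenever both members of the current pair are still present, the member
    with the smaller mean distance to the remaining survivors is removed
    (ties: the later input row). Survivors keep their original order.
    """
    n = msa.n_sequences
    if not 2 <= target_n <= n:
        raise ValueError(f"target_n must be in [2, {n}]; got {target_n}")
    if target_n == n:
        return MSA(ids=list(msa.ids), rows=list(msa.rows))
    dm = dm or distance_matrix(msa)
    d = dm.d.copy()

    pairs = sorted(
        ((d[i, j], tuple(sorted((msa.ids[i], msa.ids[j]))), i, j)
         for i in range(n) for j in range(i + 1, n)),
        key=lambda t: (t[0], t[1]),
    )
    alive = np.ones(n, dtype=bool)
    for _, _, i, j in pairs:
        if alive.sum() <= target_n:
            break
        if not (alive[i] and alive[j]):
            continue
        mask_i = alive.copy(); mask_i[i] = False; mask_i[j] = False
        mean_i = d[i, mask_i].mean() if mask_i.any() else 0.0
        mean_j = d[j, mask_i].mean() if mask_i.any() else 0.0
        # drop the member sitting closer to the rest of the set
        if mean_i < mean_j:
            drop = i
        elif mean_j < mean_i:
            drop = j
        else:
            drop = max(i, j)
        alive[drop] = False
    keep = np.flatnonzero(alive)
    return MSA(ids=[msa.ids[k] for k in keep], rows=[msa.rows[k] for k in keep])


def _column_stats(column: np.ndarray) -> tuple[np.ndarray, float, int]:
    n_rows = len(column)
    gaps = int((column == "-").sum())
    counts = np.zeros(20)
    for ch in column:
        idx = _AA_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1
    n_eff = int(counts.sum())
    freqs = counts / n_eff if n_eff else counts
    return freqs, gaps / n_rows, n_eff


def _entropy_log20(freqs: np.ndarray) -> float:
    nz = freqs[freqs > 0]
    if nz.size == 0:
        return float("nan")
    return max(0.0, float(-(nz * np.log(nz)).sum() / math.log(20.0)))


def column_entropy(msa: MSA, gap_max: float = 0.5) -> EntropyProfile:
    """Per-column log20 entropy profile of an alignment.

    Columns whose gap fraction exceeds ``gap_max`` are flagged but still
    computed; a column with zero standard residues gets S = NaN (flagged), not
    an exception.
    """
    if msa.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    rows = _row_matrix(msa)
    columns = []
    for c in range(msa.length):
        freqs, gap_frac, n_eff = _column_stats(rows[:, c])
        columns.append(
            ColumnRecord(
                frequencies=freqs,
                gap_fraction=gap_frac,
                n_effective=n_eff,
                entropy=_entropy_log20(freqs) if n_eff else float("nan"),
                gap_flagged=gap_frac > gap_max or n_eff == 0,
            )
        )
    return EntropyProfile(columns=columns)


def residue_frequencies(msa: MSA) -> np.ndarray:
    """Position-frequency table, shape (length, 20) over ``AMINO_ACIDS`` order.

    Suitable for sequence-logo rendering; rows sum to 1 for columns holding at
    least one standard residue.
    """
    rows = _row_matrix(msa)
    return np.asarray([_column_stats(rows[:, c])[0] for c in range(msa.length)])


def map_entropy_to_structure(
    profile: EntropyProfile,
    msa: MSA,
    reference_id: str,
    structure: Structure,
    chain_id: str,
    out_path=None,
    min_identity_pct: float = 80.0,
    sentinel: float = 0.0,
) -> dict[tuple[str, int, str], float]:
    """Assign each structure residue the entropy of its aligned MSA column.

    The reference MSA row is ungapped and globally aligned to the chain
    sequence; the alignment must reach ``min_identity_pct``. Returns the
    per-residue score map and, if ``out_path`` is given, also writes a PDB
    with the scores in the B-factor column (unmatched residues = sentinel).
    """
    from .superpose import global_align

    ref_row = msa.row(reference_id)  # KeyError if absent
    chain = structure.get_chain(chain_id)

    ref_columns = [c for c, ch in enumerate(ref_row) if ch != "-"]
    ref_seq = "".join(ref_row[c] for c in ref_columns)
    chain_seq = chain.sequence()
    aln = global_align(ref_seq, chain_seq)
    if aln.identity_pct < min_identity_pct:
        raise ValueError(
            f"reference/chain identity {aln.identity_pct:.1f}% below "
            f"{min_identity_pct:.1f}%\n{aln.aligned_a}\n{aln.aligned_b}"
        )

    entropies = profile.entropies
    scores: dict[tuple[str, int, str], float] = {}
    i_ref = i_chain = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-" and cb != "-":
            col = ref_columns[i_ref]
            res = chain.residues[i_chain]
            s = entropies[col]
            scores[(chain.id, res.seq_id, res.insertion_code)] = (
                sentinel if math.isnan(s) else float(s)
            )
        if ca != "-":
            i_ref += 1
        if cb != "-":
            i_chain += 1
    if out_path is not None:
        write_structure_with_scores(structure, scores, out_path, sentinel=sentinel)
    return scores
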