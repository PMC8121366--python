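"""Distance matrix, redundancy pruning, log20 entropy, and structure mapping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lobescope import (
    MSA,
    column_entropy,
    distance_matrix,
    make_ideal_helix,
    make_synthetic_msa,
    map_entropy_to_structure,
    prune_redundancy,
    read_structure,
    residue_frequencies,
    write_structure,
)
from lobescope.synth import HelixSpec

LN2_LN20 = math.log(2) / math.log(20)  # 50/50 two-residue column entropy
H_TWO_THIRDS = (math.log(3) - (2 / 3) * math.log(2)) / math.log(20)  # (2/3, 1/3) column


class TestDistanceMatrix:
    def test_identical_pair_distance_zero(self):
        msa = MSA(ids=["a", "b"], rows=["ACDE", "ACDE"])
        assert distance_matrix(msa).d[0, 1] == 0.0

    def test_half_identical(self):
        msa = MSA(ids=["a", "b"], rows=["AAAA", "AACC"])
        assert distance_matrix(msa).d[0, 1] == pytest.approx(0.5)

    def test_gaps_excluded_from_comparable_columns(self):
        msa = MSA(ids=["a", "b"], rows=["AC-E", "ACD-"])
        # comparable columns: 1 and 2, both identical
        assert distance_matrix(msa).d[0, 1] == 0.0

    def test_no_shared_columns_distance_one_with_warning(self):
        msa = MSA(ids=["a", "b"], rows=["AC--", "--DE"])
        with pytest.warns(UserWarning, match="no ungapped columns"):
            assert distance_matrix(msa).d[0, 1] == 1.0

    def test_matches_brute_force_recount(self, rng):
        synth = make_synthetic_msa(
            n_seq=10, length=30, conservation_profile=np.full(30, 0.2),
            gap_profile=np.full(30, 0.1), seed=11,
        )
        msa = synth.to_msa()
        dm = distance_matrix(msa)
        for i in range(10):
            for j in range(10):
                if i == j:
                    assert dm.d[i, j] == 0.0
                    continue
                same = comp = 0
                for a, b in zip(msa.rows[i], msa.rows[j]):
                    if a != "-" and b != "-":
                        comp += 1
                        same += a == b
                assert dm.d[i, j] == pytest.approx(1.0 - same / comp)
        np.testing.assert_allclose(dm.d, dm.d.T)


FIVE_SEQ = MSA(
    ids=["s1", "s2", "s3", "s4", "s5"],
    rows=[
        "AAAAAAAAAA",  # s1
        "AAAAAAAAAC",  # s2: d(s1,s2)=0.1  (closest pair)
        "AAAAACCCCC",  # s3
        "CCCCCCCCCC",  # s4
        "ACDEFGHIKL",  # s5: outlier
    ],
)


class TestPruneRedundancy:
    def test_exact_duplicate_later_row_removed(self):
        msa = MSA(ids=["a", "b", "c"], rows=["ACDE", "AAAA", "ACDE"])
        pruned = prune_redundancy(msa, 2)
        assert pruned.ids == ["a", "b"]

    def test_target_equal_to_n_is_identity(self):
        pruned = prune_redundancy(FIVE_SEQ, 5)
        assert pruned.ids == FIVE_SEQ.ids and pruned.rows == FIVE_SEQ.rows

    def test_hand_traced_oracle(self):
        # distances: (s1,s2)=0.1 closest; the member with the smaller mean
        # distance to the other survivors is removed.
        #   mean(s1 -> s3,s4,s5) = (0.5+1.0+0.9)/3 = 0.800
        #   mean(s2 -> s3,s4,s5) = (0.4+0.9+0.9)/3 = 0.733  -> s2 removed
        # next surviving pair (s1,s3)=0.5:
        #   mean(s1 -> s4,s5) = (1.0+0.9)/2 = 0.95
        #   mean(s3 -> s4,s5) = (0.5+0.9)/2 = 0.70           -> s3 removed
        pruned = prune_redundancy(FIVE_SEQ, 3)
        assert pruned.ids == ["s1", "s4", "s5"]

    def test_output_size_and_determinism(self):
        a = prune_redundancy(FIVE_SEQ, 2)
        b = prune_redundancy(FIVE_SEQ, 2)
        assert a.n_sequences == 2
        assert a.ids == b.ids and a.rows == b.rows

    def test_survivors_keep_input_order(self):
        pruned = prune_redundancy(FIVE_SEQ, 3)
        order = [FIVE_SEQ.ids.index(i) for i in pruned.ids]
        assert order == sorted(order)

    def test_target_out_of_range_rejected(self):
        for bad in (1, 6):
            with pytest.raises(ValueError):
                prune_redundancy(FIVE_SEQ, bad)

    def test_pruning_raises_mean_pairwise_distance(self):
        # redundant clusters: pruned survivors should be more evenly spread
        synth = make_synthetic_msa(
            n_seq=30, length=40, conservation_profile=np.full(40, 0.6),
            redundancy=(5, 2), seed=5,
        )
        msa = synth.to_msa()
        before = distance_matrix(msa)
        pruned = prune_redundancy(msa, 5)
        after = distance_matrix(pruned)
        tri = lambda d: d[np.triu_indices(len(d), 1)].mean()
        assert tri(after.d) >= tri(before.d)

    def test_cluster_representatives_survive(self):
        synth = make_synthetic_msa(
            n_seq=50, length=40, conservation_profile=np.full(40, 0.6),
            redundancy=(5, 2), seed=17,
        )
        pruned = prune_redundancy(synth.to_msa(), 5)
        clusters = {synth.cluster_of[synth.ids.index(i)] for i in pruned.ids}
        assert clusters == set(range(5))


class TestColumnEntropy:
    def test_closed_forms(self):
        msa = MSA(
            ids=[f"s{i}" for i in range(20)],
            rows=["A" + "ACDEFGHIKLMNPQRSTVWY"[i] + ("AC"[i % 2]) for i in range(20)],
        )
        profile = column_entropy(msa)
        s = profile.entropies
        assert s[0] == pytest.approx(0.0, abs=1e-12)  # fully conserved
        assert s[1] == pytest.approx(1.0, abs=1e-12)  # all 20 residues once
        assert s[2] == pytest.approx(LN2_LN20, abs=1e-12)  # 50/50 two residues

    def test_gaps_and_ambiguity_excluded_renormalized(self):
        msa = MSA(ids=["a", "b", "c", "d"], rows=["A", "A", "-", "X"])
        profile = column_entropy(msa)
        col = profile.columns[0]
        assert col.entropy == pytest.approx(0.0)
        assert col.gap_fraction == pytest.approx(0.25)
        assert col.n_effective == 2

    def test_gap_heavy_column_flagged_but_computed(self):
        msa = MSA(ids=["a", "b", "c", "d"], rows=["A", "-", "-", "-"])
        col = column_entropy(msa, gap_max=0.5).columns[0]
        assert col.gap_flagged and col.entropy == pytest.approx(0.0)

    def test_all_gap_column_nan_not_exception(self):
        msa = MSA(ids=["a", "b"], rows=["-A", "-A"])
        col = column_entropy(msa).columns[0]
        assert math.isnan(col.entropy) and col.gap_flagged

    def test_row_permutation_and_duplication_invariance(self, rng):
        synth = make_synthetic_msa(
            n_seq=20, length=15, conservation_profile=np.full(15, 0.2), seed=23,
        )
        msa = synth.to_msa()
        base = column_entropy(msa).entropies
        perm = rng.permutation(20)
        shuffled = MSA(ids=[msa.ids[k] for k in perm], rows=[msa.rows[k] for k in perm])
        np.testing.assert_allclose(column_entropy(shuffled).entropies, base, atol=1e-12)
        doubled = MSA(ids=msa.ids + [i + "_dup" for i in msa.ids], rows=msa.rows * 2)
        np.testing.assert_allclose(column_entropy(doubled).entropies, base, atol=1e-12)


class TestResidueFrequencies:
    def test_single_sequence_unit_vectors(self):
        msa = MSA(ids=["only"], rows=["AV"])
        freqs = residue_frequencies(msa)
        assert freqs.shape == (2, 20)
        assert freqs[0].max() == 1.0 and freqs[1].max() == 1.0

    def test_known_small_alignment(self):
        from lobescope.conservation import AMINO_ACIDS

        msa = MSA(ids=["a", "b"], rows=["AV", "AV"])
        freqs = residue_frequencies(msa)
        assert freqs[0, AMINO_ACIDS.index("A")] == 1.0
        assert freqs[1, AMINO_ACIDS.index("V")] == 1.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_frequencies_sum_to_one(self, seed):
        synth = make_synthetic_msa(
            n_seq=8, length=10, conservation_profile=np.full(10, 0.15),
            gap_profile=np.full(10, 0.2), seed=seed,
        )
        freqs = residue_frequencies(synth.to_msa())
        sums = freqs.sum(axis=1)
        assert np.all((np.abs(sums - 1.0) < 1e-9) | (sums == 0.0))


def _helix_with_sequence(seq):
    return make_ideal_helix(HelixSpec(n_res=len(seq), sequence=seq))


class TestMapEntropy:
    SEQ = "ACDEFGHIKLMNPQRSTVWY"

    def _msa(self):
        rows = [self.SEQ, self.SEQ[:5] + "V" + self.SEQ[6:], self.SEQ]
        return MSA(ids=["ref", "homolog", "other"], rows=rows)

    def test_identical_sequence_maps_column_entropy(self):
        msa = self._msa()
        profile = column_entropy(msa)
        structure = _helix_with_sequence(self.SEQ)
        scores = map_entropy_to_structure(profile, msa, "ref", structure, "A")
        assert len(scores) == 20
        # column 6 mixes G (2/3) and V (1/3) across the three rows
        assert scores[("A", 6, "")] == pytest.approx(H_TWO_THIRDS, abs=1e-9)
        assert scores[("A", 1, "")] == pytest.approx(0.0, abs=1e-12)

    def test_fully_conserved_msa_maps_zero_everywhere(self, tmp_path):
        msa = MSA(ids=["ref", "b"], rows=[self.SEQ, self.SEQ])
        profile = column_entropy(msa)
        structure = _helix_with_sequence(self.SEQ)
        out = tmp_path / "scored.pdb"
        map_entropy_to_structure(profile, msa, "ref", structure, "A", out_path=out)
        back = read_structure(out)
        assert all(
            res.atoms[0].bfactor == pytest.approx(0.0, abs=1e-9)
            for res in back.get_chain("A").residues
        )

    def test_truncated_structure_mapping_offset(self):
        msa = self._msa()
        profile = column_entropy(msa)
        full = _helix_with_sequence(self.SEQ)
        truncated_chain = full.get_chain("A")
        truncated_chain.residues = truncated_chain.residues[3:]
        scores = map_entropy_to_structure(profile, msa, "ref", full, "A")
        # residue with seq_id 6 still corresponds to MSA column 6 (variable)
        assert len(scores) == 17
        assert scores[("A", 6, "")] == pytest.approx(H_TWO_THIRDS, abs=1e-9)
        assert ("A", 1, "") not in scores

    def test_missing_reference_id_rejected(self):
        msa = self._msa()
        profile = column_entropy(msa)
        with pytest.raises(KeyError):
            map_entropy_to_structure(profile, msa, "nope", _helix_with_sequence(self.SEQ), "A")

    def test_low_identity_rejected_with_alignment(self):
        msa = MSA(ids=["ref", "b"], rows=["WWWWWWWWWWWWWWWWWWWW", "WWWWWWWWWWWWWWWWWWWW"])
        profile = column_entropy(msa)
        structure = _helix_with_sequence(self.SEQ)
        with pytest.raises(ValueError, match="identity"):
            map_entropy_to_structure(profile, msa, "ref", structure, "A")

    def test_entropy_profile_roundtrip_through_bfactors(self, tmp_path):
        synth = make_synthetic_msa(
            n_seq=40, length=20, conservation_profile=np.linspace(0.0, 0.2, 20), seed=3,
        )
        msa = synth.to_msa()
        ref_row = msa.rows[0].replace("-", "")
        profile = column_entropy(msa)
        # structure whose sequence equals the (ungapped) reference row
        structure = _helix_with_sequence(ref_row)
        out = tmp_path / "scored.pdb"
        scores = map_entropy_to_structure(profile, msa, msa.ids[0], structure, "A", out_path=out)
        back = read_structure(out)
        for res in back.get_chain("A").residues:
            assert res.atoms[0].bfactor == pytest.approx(
                scores[("A", res.seq_id, "")], abs=0.01
            )
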