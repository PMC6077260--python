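"""Clonal clustering, ranking, MSA, consensus, representative and logos."""

import numpy as np
import pytest

from igkit.annotate import AnnotationRecord
from igkit.clonal import (
    Clone,
    align_clone_members,
    analyze_clone,
    clone_consensus,
    cluster_clones,
    expansion_table,
    most_similar_member,
    sequence_logo_matrix,
    top_k_clones,
)


def _record(aa, cdr3, count=1, nt=None):
    return AnnotationRecord(
        chain="VH",
        isotype="IgM",
        nt_sequence=nt or "ATG",
        aa_sequence=aa,
        cdr3_aa=cdr3,
        v_subgroup="IGHV1",
        d_subgroup="none",
        j_subgroup="IGHJ1",
        count=count,
    )


class TestClusterClones:
    def test_x_and_y_match_enumeration_oracle(self):
        records = [
            _record("AAA", "CAR", count=2),
            _record("AAC", "CAR", count=3),
            _record("AAD", "CAR", count=4),
        ]
        clones = cluster_clones(records)
        assert len(clones) == 1
        assert clones[0].x == 3
        assert clones[0].y == 9

    def test_single_record_clone(self):
        clones = cluster_clones([_record("AAA", "CAR", count=5)])
        assert (clones[0].x, clones[0].y) == (1, 5)

    def test_clustering_is_at_amino_acid_level(self):
        # same CDRH3 peptide from two different nucleotide junctions
        records = [
            _record("AAA", "CAR", nt="GCTGCTGCT"),
            _record("AAC", "CAR", nt="GCAGCAGCA"),
        ]
        assert len(cluster_clones(records)) == 1

    def test_records_without_cdr3_excluded(self):
        clones = cluster_clones([_record("AAA", ""), _record("AAC", "CAR")])
        assert len(clones) == 1

    @pytest.mark.parametrize("n_records", [10, 100])
    def test_conservation_invariants(self, n_records):
        rng = np.random.default_rng(n_records)
        records = [
            _record(
                "".join(rng.choice(list("ACDEF"), 8)),
                "".join(rng.choice(list("CARW"), 4)),
                count=int(rng.integers(1, 9)),
            )
            for _ in range(n_records)
        ]
        # records sharing (cdr3, aa) are distinct records here, so dedupe first
        seen = {}
        for r in records:
            seen.setdefault((r.cdr3_aa, r.aa_sequence), r)
        records = list(seen.values())
        clones = cluster_clones(records)
        assert sum(c.y for c in clones) == sum(r.count for r in records)
        assert sum(c.x for c in clones) == len(records)
        assert all(c.x <= c.y for c in clones)


class TestTopK:
    def _clones(self, n):
        return [
            Clone(cdrh3_aa=f"CAR{i:03d}", members=[("A", i + 1, "GCT")]) for i in range(n)
        ]

    def test_default_k_truncates_at_100(self):
        assert len(top_k_clones(self._clones(150))) == 100

    def test_small_input_passes_through(self):
        assert len(top_k_clones(self._clones(3))) == 3

    def test_ordering_and_tie_break_determinism(self):
        clones = [
            Clone("CARB", [("A", 5, "G")]),
            Clone("CARA", [("A", 5, "G")]),
            Clone("CARC", [("A", 3, "G"), ("B", 2, "G")]),  # same y, higher x
        ]
        ranked = top_k_clones(clones)
        assert [c.cdrh3_aa for c in ranked] == ["CARC", "CARA", "CARB"]
        # ranking is invariant to input order
        assert [c.cdrh3_aa for c in top_k_clones(clones[::-1])] == ["CARC", "CARA", "CARB"]

    def test_top_k_is_prefix_of_full_sort(self):
        clones = self._clones(30)
        full = top_k_clones(clones, k=30)
        assert top_k_clones(clones, k=10) == full[:10]


class TestMsaAndConsensus:
    def test_identical_members_gap_free(self):
        clone = Clone("CAR", [("MAAAK", 3, "X"), ("MAAAK", 2, "X")])
        msa = align_clone_members(clone)
        assert msa == ["MAAAK", "MAAAK"]
        assert clone_consensus(msa) == "MAAAK"

    def test_internal_insertion_becomes_gap_block(self):
        clone = Clone("CAR", [("MAKLWDAEK", 5, "X"), ("MAKLWGSDAEK", 1, "X")])
        msa = align_clone_members(clone)
        assert len(msa[0]) == len(msa[1]) == 11
        assert msa[0].count("-") == 2  # one 2-column gap block in the center row
        assert "--" in msa[0]
        assert msa[1] == "MAKLWGSDAEK"

    def test_singleton_clone(self):
        clone = Clone("CAR", [("MAK", 1, "X")])
        assert align_clone_members(clone) == ["MAK"]

    def test_consensus_column_vote(self):
        msa = ["MAAAK", "MAAAK", "MAAAK", "MAAAK", "MASAK"]
        # column 2: A x4 vs S x1 -> A
        assert clone_consensus(msa) == "MAAAK"

    def test_consensus_drops_gap_majority_columns(self):
        msa = ["MA-K", "MA-K", "MAWK"]
        assert clone_consensus(msa) == "MAK"

    def test_consensus_of_gap_free_msa_keeps_row_length(self):
        msa = ["MAAAK", "MACAK", "MAADK"]
        assert len(clone_consensus(msa)) == 5


class TestRepresentative:
    def test_member_equal_to_consensus_wins(self):
        clone = Clone(
            "CAR",
            [("MAAAK", 1, "nt1"), ("MACAK", 1, "nt2"), ("MAAAC", 1, "nt3")],
        )
        msa = align_clone_members(clone)
        consensus = clone_consensus(msa)
        rep, sim, nt = most_similar_member(clone, consensus)
        assert consensus == "MAAAK"
        assert rep == "MAAAK"
        assert sim == 1.0
        assert nt == "nt1"

    def test_singleton_similarity_is_one(self):
        clone = Clone("CAR", [("MAK", 4, "nt")])
        clone = analyze_clone(clone)
        assert clone.representative_aa == "MAK"
        assert clone.similarity == 1.0
        assert clone.consensus_aa == "MAK"

    def test_exhaustive_comparison_oracle(self):
        members = [("MAAAKLLT", 2, "a"), ("MAAAKLIT", 1, "b"), ("MWWAKLIT", 1, "c")]
        clone = analyze_clone(Clone("CAR", list(members)))
        # oracle: per-member identity fraction against the column-vote consensus
        cons = clone.consensus_aa
        sims = {
            aa: sum(x == y for x, y in zip(aa, cons)) / len(cons) for aa, _, _ in members
        }
        best = max(sims.values())
        assert clone.similarity == pytest.approx(best)
        assert sims[clone.representative_aa] == pytest.approx(best)


class TestLogoMatrix:
    def test_identical_members_unit_columns(self):
        msa = ["MAK", "MAK"]
        logo = sequence_logo_matrix(msa)
        assert set(logo["frequency"]) == {1.0}
        assert list(logo["position"].unique()) == [0, 1, 2]

    def test_count_weighted_split(self):
        msa = ["MAK", "MCK"]
        logo = sequence_logo_matrix(msa, weights=[1, 1])
        col1 = logo[logo["position"] == 1]
        assert dict(zip(col1["residue"], col1["frequency"])) == {"A": 0.5, "C": 0.5}
        weighted = sequence_logo_matrix(msa, weights=[3, 1])
        col1 = weighted[weighted["position"] == 1]
        assert dict(zip(col1["residue"], col1["frequency"])) == {"A": 0.75, "C": 0.25}

    def test_empty_msa(self):
        assert sequence_logo_matrix([]).empty


class TestExpansionTable:
    def test_rank_columns(self):
        clones = [Clone("CARA", [("A", 2, "n")]), Clone("CARB", [("A", 7, "n")])]
        table = expansion_table(clones)
        assert list(table["rank"]) == [1, 2]
        assert list(table["y_reads"]) == [7, 2]
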