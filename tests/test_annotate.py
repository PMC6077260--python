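"""V(D)J assignment, region delineation, record grouping and AIRR ingestion."""

import numpy as np
import pytest

from igkit import (
    AnnotationError,
    Annotator,
    GermlineGene,
    GermlineSet,
    assign_d,
    assign_v_j,
    build_annotation_records,
    ingest_airr,
)
from igkit.annotate import delineate_regions
from igkit.errors import InputError
from igkit.simulate import encode_aa

from conftest import merged_from


def _construct_read(germlines, v_idx=0, j_idx=0, junction="", const=""):
    v = germlines.select("IGH", "V")[v_idx]
    j = germlines.select("IGH", "J")[j_idx]
    return merged_from(v.sequence + junction + j.sequence + const), v, j


class TestAssignVJ:
    def test_exact_construction_recovers_alleles(self, germlines):
        read, v, j = _construct_read(germlines, v_idx=2, j_idx=1, junction="GCTGCT")
        v_call, j_call, orf = assign_v_j(read, germlines, "IGH")
        assert v_call.allele_name == v.allele_name
        assert j_call.allele_name == j.allele_name
        assert v_call.mutation_count == 0
        assert j_call.mutation_count == 0
        assert orf == 0

    def test_substitutions_counted_against_known_alignment(self, germlines):
        read, v, j = _construct_read(germlines, junction="GCTGCT")
        seq = list(read.sequence)
        for pos in (10, 50, 100):  # Hamming oracle: 3 substituted positions
            seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        mutated = merged_from("".join(seq))
        v_call, j_call, _ = assign_v_j(mutated, germlines, "IGH")
        assert v_call.allele_name == v.allele_name
        assert v_call.mutation_count == 3

    def test_random_read_unannotatable(self, germlines):
        rng = np.random.default_rng(3)
        read = merged_from("".join(rng.choice(list("ACGT"), size=350)))
        with pytest.raises(AnnotationError, match="unannotatable"):
            assign_v_j(read, germlines, "IGH")

    def test_fr_substitutions_leave_calls_stable(self, germlines):
        """<=5 substitutions confined to the frameworks never change the call
        and are all recovered in the V mutation count."""
        rng = np.random.default_rng(9)
        for k in range(1, 6):
            read, v, j = _construct_read(germlines, junction="GCAGCA")
            seq = list(read.sequence)
            positions = rng.choice(280, size=k, replace=False)  # inside FR1-FR3
            for pos in positions:
                seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
            v_call, j_call, _ = assign_v_j(merged_from("".join(seq)), germlines, "IGH")
            assert (v_call.allele_name, j_call.allele_name) == (v.allele_name, j.allele_name)
            assert v_call.mutation_count + j_call.mutation_count == k


class TestAssignD:
    def test_long_exact_block_found(self, germlines):
        d = germlines.select("IGH", "D")[1]
        junction = "AC" + d.sequence[2:11] + "GT"  # 9-nt exact block
        call = assign_d(junction, germlines)
        assert call is not None
        assert call.allele_name == d.allele_name

    def test_short_match_below_threshold(self, germlines):
        d = germlines.select("IGH", "D")[0]
        junction = d.sequence[:4]
        assert assign_d(junction, germlines, min_d_match=5) is None

    def test_empty_junction(self, germlines):
        assert assign_d("", germlines) is None


class TestDelineateRegions:
    def test_exact_construction_cdr3(self, germlines, sim_config):
        junction = encode_aa("DY")
        read, v, j = _construct_read(germlines, junction=junction)
        v_call, j_call, orf = assign_v_j(read, germlines, "IGH")
        rm = delineate_regions(read, v_call, j_call, v.cdr3_anchor, j.cdr3_anchor, orf)
        # CDR3 = V from its Cys anchor + junction + J through its Trp anchor codon
        expected = (
            v.sequence[v.cdr3_anchor :] + junction + j.sequence[: j.cdr3_anchor + 3]
        )
        assert read.sequence[rm.cdr3_start : rm.cdr3_end] == expected

    def test_minimal_anchor_germlines_zero_junction(self):
        """With anchors at the V end / J start, an empty junction leaves a CDR3
        of exactly the two anchor codons."""
        v = GermlineGene("IGHV1-1*01", "V", "IGH", "GCT" * 20 + "TGT", "IGHV1", 60)
        j = GermlineGene("IGHJ1*01", "J", "IGH", "TGG" + "GGT" * 12, "IGHJ1", 0)
        gset = GermlineSet("human", [v, j])
        read = merged_from(v.sequence + j.sequence)
        v_call, j_call, orf = assign_v_j(read, gset, "IGH", score_floor=40)
        rm = delineate_regions(read, v_call, j_call, 60, 0, orf)
        assert read.sequence[rm.cdr3_start : rm.cdr3_end] == "TGTTGG"

    def test_anchor_not_covered_flagged(self, germlines):
        v = germlines.select("IGH", "V")[0]
        j = germlines.select("IGH", "J")[0]
        read, _, _ = _construct_read(germlines, junction="GCTGCT")
        v_call, j_call, orf = assign_v_j(read, germlines, "IGH")
        # V alignment artificially truncated before the Cys anchor
        v_call.alignment = [p for p in v_call.alignment if p[1] < v.cdr3_anchor]
        with pytest.raises(AnnotationError, match="cdr3-undefined"):
            delineate_regions(read, v_call, j_call, v.cdr3_anchor, j.cdr3_anchor, orf)


class TestAnnotatorRoundTrip:
    def test_zero_noise_recovery_is_exact(self, germlines, clean_repertoire):
        """No SHM, no sequencing error: every read's V/J alleles and CDR3 are
        recovered exactly (simulator ground truth as oracle)."""
        reads, truth = clean_repertoire
        annotator = Annotator(germlines)
        by_amplicon = truth.drop_duplicates("amplicon").set_index("amplicon")
        seen = set()
        for r in reads:
            if r.amplicon in seen:
                continue
            seen.add(r.amplicon)
            ann = annotator.annotate(merged_from(r.amplicon))
            assert ann is not None
            row = by_amplicon.loc[r.amplicon]
            assert ann.v_call.allele_name == row.v_allele
            assert ann.j_call.allele_name == row.j_allele
            assert ann.cdr3_aa == row.cdr3_aa
            assert ann.v_call.mutation_count == 0
            assert not ann.has_stop


class TestBuildRecords:
    def _annotated(self, annotator, seq, count=1, indices=None):
        read = merged_from(seq, count=count, indices=indices or [0])
        ann = annotator.annotate(read)
        assert ann is not None
        return ann

    def test_synonymous_variants_group_to_one_record(self, germlines):
        annotator = Annotator(germlines)
        v = germlines.select("IGH", "V")[0]
        j = germlines.select("IGH", "J")[0]
        # CTG and CTC both encode Leu: same AA sequence, two nt variants
        a = self._annotated(annotator, v.sequence + "CTG" + j.sequence, count=2, indices=[0, 1])
        b = self._annotated(annotator, v.sequence + "CTC" + j.sequence, count=3, indices=[2, 3, 4])
        records = build_annotation_records([a, b])
        assert len(records) == 1
        assert records[0].count == 5
        assert records[0].nt_sequence.startswith(v.sequence[:50])
        assert len(records[0].members) == 2

    def test_single_read_single_record(self, germlines):
        annotator = Annotator(germlines)
        v = germlines.select("IGH", "V")[0]
        j = germlines.select("IGH", "J")[0]
        a = self._annotated(annotator, v.sequence + "CTG" + j.sequence)
        records = build_annotation_records([a])
        assert len(records) == 1
        assert records[0].count == 1

    def test_isotype_is_part_of_grouping_key(self, germlines):
        annotator = Annotator(germlines)
        v = germlines.select("IGH", "V")[0]
        j = germlines.select("IGH", "J")[0]
        a = self._annotated(annotator, v.sequence + "CTG" + j.sequence)
        b = self._annotated(annotator, v.sequence + "CTG" + j.sequence)
        a.isotype, b.isotype = "IgM", "IgG"
        records = build_annotation_records([a, b])
        # grouping-key oracle: keys {(VH, IgM, aa), (VH, IgG, aa)} -> 2 records
        assert len(records) == 2
        assert {r.isotype for r in records} == {"IgM", "IgG"}


class TestIngestAirr:
    def _write(self, tmp_path, rows, columns=None):
        import pandas as pd

        columns = columns or [
            "sequence",
            "sequence_aa",
            "v_call",
            "d_call",
            "j_call",
            "junction_aa",
            "duplicate_count",
        ]
        p = tmp_path / "airr.tsv"
        pd.DataFrame(rows, columns=columns).to_csv(p, sep="\t", index=False)
        return p

    def test_well_formed_rows_become_records(self, tmp_path):
        rows = [
            ("ATGGCT", "MA", "IGHV1-1*01", "IGHD1-1*01", "IGHJ1*01", "CAR", 4),
            ("ATGGCA", "MA", "IGHV1-1*01", "", "IGHJ1*01", "CAR", 2),
            ("ATGTGT", "MC", "IGHV3-1*01", "", "IGHJ2*01", "CGK", 1),
        ]
        records = ingest_airr(self._write(tmp_path, rows))
        assert len(records) == 2  # first two rows share the AA sequence
        by_aa = {r.aa_sequence: r for r in records}
        assert by_aa["MA"].count == 6
        assert by_aa["MA"].v_subgroup == "IGHV1"
        assert by_aa["MC"].j_subgroup == "IGHJ2"

    def test_stop_codon_rows_dropped(self, tmp_path):
        rows = [
            ("ATGTAA", "M*", "IGHV1-1*01", "", "IGHJ1*01", "CAR", 1),
            ("ATGGCT", "MA", "IGHV1-1*01", "", "IGHJ1*01", "CAR", 1),
        ]
        records = ingest_airr(self._write(tmp_path, rows))
        assert [r.aa_sequence for r in records] == ["MA"]

    def test_missing_mandatory_column_is_an_error(self, tmp_path):
        p = self._write(
            tmp_path,
            [("ATG", "M", "IGHJ1*01", "CAR")],
            columns=["sequence", "sequence_aa", "j_call", "junction_aa"],
        )
        with pytest.raises(InputError, match="v_call"):
            ingest_airr(p)
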