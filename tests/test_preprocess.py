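"""Merging, UMI handling and filtering."""

import numpy as np
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

from igkit.preprocess import (
    FilterConfig,
    MergedRead,
    ReadPair,
    apply_filters,
    collapse_umi_groups,
    extract_umi,
    merge_pair,
    reverse_complement,
)

from conftest import merged_from, pair_from_amplicon


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestMergePair:
    def test_identical_full_overlap(self):
        seq = "ACGTACGTACGTACGTACGTACGT"
        pair = ReadPair(
            read_index=0,
            fwd_seq=seq,
            rev_seq=reverse_complement(seq),
            fwd_qual=tuple([30] * len(seq)),
            rev_qual=tuple([37] * len(seq)),
        )
        merged = merge_pair(pair, min_overlap=10)
        assert merged.sequence == seq
        assert merged.quality == tuple([37] * len(seq))  # elementwise max

    def test_constructed_overlap_recovers_template(self):
        rng = np.random.default_rng(5)
        template = _random_seq(rng, 400)
        pair = pair_from_amplicon(template, read_length=250)
        merged = merge_pair(pair)
        assert merged.sequence == template

        # brute-force oracle: the unique zero-mismatch offset
        fwd, rc = pair.fwd_seq, reverse_complement(pair.rev_seq)
        zero_mismatch = [
            k
            for k in range(len(fwd) - 20 + 1)
            if all(
                a == b
                for a, b in zip(fwd[k:], rc[: min(len(fwd) - k, len(rc))])
            )
        ]
        assert zero_mismatch == [len(template) - 250]

    def test_non_overlapping_reads_signal(self):
        rng = np.random.default_rng(6)
        pair = ReadPair(
            read_index=0,
            fwd_seq=_random_seq(rng, 250),
            rev_seq=_random_seq(rng, 250),
            fwd_qual=tuple([30] * 250),
            rev_qual=tuple([30] * 250),
        )
        assert merge_pair(pair) is None

    def test_disagreement_resolved_by_quality(self):
        seq = "ACGTACGTACGTACGTACGTACGT"
        other = "T" + seq[1:]
        pair = ReadPair(
            read_index=0,
            fwd_seq=seq,
            rev_seq=reverse_complement(other),
            fwd_qual=tuple([20] * len(seq)),
            rev_qual=tuple([39] * len(seq)),
        )
        merged = merge_pair(pair, min_overlap=10)
        assert merged.sequence == other  # reverse mate wins on quality
        # forward mate wins ties
        pair_tie = ReadPair(
            read_index=0,
            fwd_seq=seq,
            rev_seq=reverse_complement(other),
            fwd_qual=tuple([30] * len(seq)),
            rev_qual=tuple([30] * len(seq)),
        )
        assert merge_pair(pair_tie, min_overlap=10).sequence == seq

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_simulated_amplicon_always_recovered(self, trial_seed):
        """Error-free mates with sufficient overlap reconstruct the template."""
        rng = np.random.default_rng(trial_seed)
        length = int(rng.integers(300, 460))
        template = _random_seq(rng, length)
        merged = merge_pair(pair_from_amplicon(template, read_length=250))
        assert merged is not None and merged.sequence == template


class TestExtractUmi:
    def test_pure_capture_and_trim(self):
        pair = ReadPair(0, "ACGTTTTTTTTT", "GGGGGGGG", tuple([30] * 12), tuple([30] * 8))
        umi, trimmed = extract_umi(pair, "NNNN", "forward")
        assert umi == "ACGT"
        assert trimmed.fwd_seq == "TTTTTTTT"
        assert len(trimmed.fwd_qual) == 8

    def test_fixed_base_mismatch_unmatched(self):
        pair = ReadPair(0, "AACGTTTT", "GGGGGGGG", tuple([30] * 8), tuple([30] * 8))
        assert extract_umi(pair, "TNNN", "forward") is None

    def test_both_mates_concatenate_forward_first(self):
        pair = ReadPair(0, "ACTTTTTT", "GGAAAAAA", tuple([30] * 8), tuple([30] * 8))
        umi, trimmed = extract_umi(pair, "NN", "both")
        assert umi == "ACGG"
        assert trimmed.fwd_seq == "TTTTTT"
        assert trimmed.rev_seq == "AAAAAA"

    def test_pattern_longer_than_read_unmatched(self):
        pair = ReadPair(0, "ACG", "GGG", tuple([30] * 3), tuple([30] * 3))
        assert extract_umi(pair, "NNNNN", "forward") is None


def _vote_oracle(seqs: list[str]) -> str:
    """Independent per-column majority with alphabetical ties (equal quality)."""
    out = []
    for col in zip(*seqs):
        counts = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        best = max(counts.values())
        out.append(sorted(ch for ch in counts if counts[ch] == best)[0])
    return "".join(out)


class TestCollapseUmiGroups:
    def test_identical_group_collapses_with_count(self):
        reads = [merged_from("ACGTACGT", umi="AAAA", indices=[i]) for i in range(5)]
        out = collapse_umi_groups(reads)
        assert len(out) == 1
        assert out[0].sequence == "ACGTACGT"
        assert out[0].count == 5
        assert sorted(out[0].read_indices) == [0, 1, 2, 3, 4]

    def test_single_substitution_outvoted(self):
        reads = [merged_from("ACGTACGT", umi="AAAA") for _ in range(4)]
        reads.append(merged_from("ACGAACGT", umi="AAAA"))
        out = collapse_umi_groups(reads)
        assert len(out) == 1
        assert out[0].sequence == "ACGTACGT"

    def test_distinct_umis_never_merge(self):
        reads = [merged_from("ACGT", umi="AAAA"), merged_from("ACGT", umi="CCCC")]
        assert len(collapse_umi_groups(reads)) == 2

    def test_off_length_reads_become_singletons(self):
        reads = [merged_from("ACGTACGT", umi="AAAA") for _ in range(3)]
        reads.append(merged_from("ACGTA", umi="AAAA"))
        out = collapse_umi_groups(reads)
        assert sorted(len(r.sequence) for r in out) == [5, 8]
        assert sum(r.count for r in out) == 4

    def test_empty_input(self):
        assert collapse_umi_groups([]) == []

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_majority_recovery_matches_vote_oracle(self, trial_seed):
        """A group with a clear error-free majority reproduces the truth,
        matching the independent per-column vote oracle."""
        rng = np.random.default_rng(trial_seed)
        truth = _random_seq(rng, 60)
        n = int(rng.integers(3, 9))
        n_clean = n // 2 + 1
        seqs = [truth] * n_clean
        for _ in range(n - n_clean):
            pos = int(rng.integers(60))
            base = rng.choice([b for b in "ACGT" if b != truth[pos]])
            seqs.append(truth[:pos] + base + truth[pos + 1 :])
        reads = [merged_from(s, umi="ACGT", indices=[i]) for i, s in enumerate(seqs)]
        out = collapse_umi_groups(reads)
        assert len(out) == 1
        assert out[0].sequence == truth == _vote_oracle(seqs)
        assert out[0].count == n


class _Stub:
    def __init__(self, length, qual=30, has_stop=False):
        self.merged = merged_from("A" * length, qual=qual)
        self.has_stop = has_stop


class TestApplyFilters:
    def test_length_boundary(self):
        retained, report = apply_filters([_Stub(300), _Stub(299)], FilterConfig())
        assert report.retained_count == 1
        assert report.rejected_short == 1

    def test_quality_boundary(self):
        retained, report = apply_filters(
            [_Stub(300, qual=20), _Stub(300, qual=19)], FilterConfig()
        )
        assert report.retained_count == 1
        assert report.rejected_low_quality == 1

    def test_stop_codon_counted_first(self):
        # fails both the stop-codon and the length criteria; counted once,
        # under the stop-codon criterion
        retained, report = apply_filters([_Stub(200, has_stop=True)], FilterConfig())
        assert report.rejected_stop_codon == 1
        assert report.rejected_short == 0

    def test_no_overlap_count_forwarded(self):
        retained, report = apply_filters([_Stub(300)], FilterConfig(), no_overlap_count=7)
        assert report.rejected_no_overlap == 7
        assert report.input_count == 8

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_conservation_on_random_batches(self, trial_seed):
        """input == retained + sum of rejections, whatever the batch."""
        rng = np.random.default_rng(trial_seed)
        stubs = [
            _Stub(
                int(rng.integers(250, 350)),
                qual=int(rng.integers(10, 40)),
                has_stop=bool(rng.random() < 0.2),
            )
            for _ in range(int(rng.integers(0, 50)))
        ]
        no_overlap = int(rng.integers(0, 10))
        _, report = apply_filters(stubs, FilterConfig(), no_overlap)
        report.check()  # asserts the conservation invariant
        assert report.input_count == len(stubs) + no_overlap
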