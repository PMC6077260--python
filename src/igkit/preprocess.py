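"""Paired-end merging, UMI handling, and read filtering.

The preprocessing stage turns raw paired-end FASTQ mates into merged
variable-region sequences ready for annotation:

1. optional UMI extraction from the 5' end of the forward and/or reverse mate
   (IUPAC pattern; fixed positions must match, degenerate positions are
   captured into the UMI);
2. overlap merging of the two mates (the reverse mate is reverse-complemented
   and the best-scoring overlap offset is taken; disagreements resolved by
   Phred quality);
3. optional UMI consensus collapsing (reads sharing a UMI become one consensus
   molecule, correcting amplification/sequencing errors);
4. filtering on four criteria: (1) stop codon in the variable-region ORF,
   (2) mates do not overlap, (3) merged sequence shorter than ``min_length``
   (default 300 nt), (4) mean read quality below ``min_quality`` (default 20).

Criterion (2) is consumed at merge time; criterion (1) requires the annotated
reading frame and is therefore applied after annotation.  A record failing
several criteria is counted once, under the first failing criterion in the
order (1), (3), (4), so the filter report partitions the input exactly.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError

# IUPAC nucleotide codes -> the set of bases each matches
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read, qualities already Phred+33-decoded."""

    read_index: int
    fwd_seq: str
    rev_seq: str
    fwd_qual: tuple[int, ...]
    rev_qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(self.rev_qual):
            raise InputError(f"read {self.read_index}: sequence/quality length mismatch")


@dataclass
class MergedRead:
    """An overlap-merged (and possibly UMI-collapsed) molecule."""

    sequence: str
    quality: tuple[int, ...]
    umi: str | None = None
    read_indices: list[int] = field(default_factory=list)
    count: int = 1

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.quality)) if self.quality else 0.0


@dataclass
class FilterConfig:
    """Thresholds for the four filtering criteria.

    ``min_length`` and ``min_quality`` carry the pipeline defaults of 300 nt
    and mean Phred 20.  ``quality_aggregate`` selects how "read quality" is
    summarized: ``"mean"`` (default) or ``"min"`` per-base quality.
    """

    min_length: int = 300
    min_quality: float = 20.0
    require_overlap: bool = True
    reject_stop_codons: bool = True
    quality_aggregate: str = "mean"

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise InputError("min_length must be positive")
        if not 0 <= self.min_quality <= 41:
            raise InputError("min_quality must be within [0, 41]")
        if self.quality_aggregate not in ("mean", "min"):
            raise InputError("quality_aggregate must be 'mean' or 'min'")


@dataclass
class FilterReport:
    input_count: int = 0
    rejected_no_overlap: int = 0
    rejected_stop_codon: int = 0
    rejected_short: int = 0
    rejected_low_quality: int = 0
    retained_count: int = 0

    def check(self) -> None:
        total = (
            self.retained_count
            + self.rejected_no_overlap
            + self.rejected_stop_codon
            + self.rejected_short
            + self.rejected_low_quality
        )
        assert total == self.input_count, (
            f"filter report does not partition input: {total} != {self.input_count}"
        )

    def as_rows(self) -> list[tuple[str, int]]:
        return [
            ("input", self.input_count),
            ("rejected_no_overlap", self.rejected_no_overlap),
            ("rejected_stop_codon", self.rejected_stop_codon),
            ("rejected_short", self.rejected_short),
            ("rejected_low_quality", self.rejected_low_quality),
            ("retained", self.retained_count),
        ]


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_pair(
    pair: ReadPair,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> MergedRead | None:
    """Merge a read pair at the best-scoring overlap offset.

    The reverse mate is reverse-complemented and slid along the forward mate;
    for each offset with overlap >= ``min_overlap`` the overlap is scored as
    matches minus mismatches, and offsets whose mismatch fraction exceeds
    ``max_mismatch_frac`` are discarded.  At disagreeing overlap positions the
    base with the higher Phred score wins (ties: forward mate) and the
    retained quality is the elementwise maximum.  Returns ``None`` when no
    acceptable overlap exists (filter criterion "mates do not overlap").
    """
    if not pair.fwd_seq or not pair.rev_seq:
        raise InputError(f"read {pair.read_index}: empty mate")
    fwd = pair.fwd_seq
    rc = reverse_complement(pair.rev_seq)
    rc_qual = pair.rev_qual[::-1]
    f = np.frombuffer(fwd.encode(), dtype=np.uint8)
    r = np.frombuffer(rc.encode(), dtype=np.uint8)
    m, n = len(f), len(r)

    best: tuple[int, int, int] | None = None  # (score, -offset, overlap)
    for k in range(0, m - min_overlap + 1):
        ov = min(m - k, n)
        mism = int(np.count_nonzero(f[k : k + ov] != r[:ov]))
        if mism > max_mismatch_frac * ov:
            continue
        score = (ov - mism) - mism
        cand = (score, -k, ov)
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    score, neg_k, ov = best
    k = -neg_k

    fq = np.asarray(pair.fwd_qual, dtype=np.int16)
    rq = np.asarray(rc_qual, dtype=np.int16)
    merged = list(fwd[:k])
    qual = list(pair.fwd_qual[:k])
    for i in range(ov):
        a, b = fwd[k + i], rc[i]
        qa, qb = int(fq[k + i]), int(rq[i])
        if a == b:
            merged.append(a)
        else:
            merged.append(a if qa >= qb else b)
        qual.append(max(qa, qb))
    merged.extend(rc[ov:])
    qual.extend(rc_qual[ov:])
    return MergedRead(
        sequence="".join(merged),
        quality=tuple(qual),
        read_indices=[pair.read_index],
        count=1,
    )


# ---------------------------------------------------------------------------
# UMIs
# ---------------------------------------------------------------------------

def _match_prefix(seq: str, pattern: str) -> str | None:
    """Match an IUPAC pattern against the 5' prefix; return captured bases."""
    if len(seq) < len(pattern):
        return None
    captured = []
    for base, code in zip(seq, pattern):
        allowed = IUPAC.get(code)
        if allowed is None:
            raise InputError(f"invalid IUPAC code {code!r} in UMI pattern")
        if code in "ACGT":
            if base != code:
                return None
        else:
            if base not in allowed:
                return None
            captured.append(base)
    return "".join(captured)


def extract_umi(
    pair: ReadPair, pattern: str, location: str = "forward"
) -> tuple[str, ReadPair] | None:
    """Extract a UMI from the 5' prefix of the targeted mate(s).

    Fixed pattern positions must match the read exactly; degenerate positions
    capture the read base.  When ``location == "both"`` the two captures are
    concatenated forward-first.  Matched prefixes are trimmed.  Returns
    ``None`` when the pattern does not match (the read is excluded and
    counted as umi-unmatched upstream).
    """
    if not pattern:
        raise InputError("empty UMI pattern")
    if location not in ("forward", "reverse", "both"):
        raise InputError(f"invalid UMI location {location!r}")
    plen = len(pattern)
    fwd_seq, fwd_qual = pair.fwd_seq, pair.fwd_qual
    rev_seq, rev_qual = pair.rev_seq, pair.rev_qual
    umi = ""
    if location in ("forward", "both"):
        cap = _match_prefix(fwd_seq, pattern)
        if cap is None:
            return None
        umi += cap
        fwd_seq, fwd_qual = fwd_seq[plen:], fwd_qual[plen:]
    if location in ("reverse", "both"):
        cap = _match_prefix(rev_seq, pattern)
        if cap is None:
            return None
        umi += cap
        rev_seq, rev_qual = rev_seq[plen:], rev_qual[plen:]
    trimmed = ReadPair(
        read_index=pair.read_index,
        fwd_seq=fwd_seq,
        rev_seq=rev_seq,
        fwd_qual=fwd_qual,
        rev_qual=rev_qual,
    )
    return umi, trimmed


def _column_vote(reads: Sequence[MergedRead]) -> MergedRead:
    """Per-position majority base over equal-length reads.

    Ties go to the base with the highest summed Phred, then alphabetical.
    Consensus quality per position is the max Phred among agreeing bases.
    """
    if len(reads) == 1:
        return reads[0]
    length = len(reads[0].sequence)
    seq_arr = np.frombuffer("".join(r.sequence for r in reads).encode(), dtype=np.uint8)
    seq_arr = seq_arr.reshape(len(reads), length)
    qual_arr = np.array([r.quality for r in reads], dtype=np.int16)
    out_seq = []
    out_qual = []
    for j in range(length):
        col = seq_arr[:, j]
        counts = Counter(col.tolist())
        best_n = max(counts.values())
        tied = [b for b, c in counts.items() if c == best_n]
        if len(tied) == 1:
            winner = tied[0]
        else:
            # highest summed Phred, then alphabetical (smaller byte)
            def keyf(b: int) -> tuple[int, int]:
                return (int(qual_arr[col == b, j].sum()), -b)

            winner = max(tied, key=keyf)
        out_seq.append(winner)
        out_qual.append(int(qual_arr[col == winner, j].max()))
    indices = [i for r in reads for i in r.read_indices]
    return MergedRead(
        sequence=bytes(out_seq).decode(),
        quality=tuple(out_qual),
        umi=reads[0].umi,
        read_indices=indices,
        count=sum(r.count for r in reads),
    )


def collapse_umi_groups(reads: Iterable[MergedRead]) -> list[MergedRead]:
    """Collapse reads sharing a UMI into per-position consensus molecules.

    Within a UMI group, reads of the group's modal length are voted into a
    single consensus; reads of any other length are kept as their own
    singletons (no rule exists for aligning unequal-length duplicates and
    they are rare).  Output ``count`` fields record group sizes, so the sum
    of counts equals the number of input reads.
    """
    groups: dict[str, list[MergedRead]] = defaultdict(list)
    for r in reads:
        if r.umi is None:
            raise InputError("collapse_umi_groups requires every read to carry a UMI")
        groups[r.umi].append(r)
    out: list[MergedRead] = []
    for umi in groups:
        members = groups[umi]
        lengths = Counter(len(r.sequence) for r in members)
        # modal length; ties broken toward the longer read for determinism
        modal = max(lengths.items(), key=lambda kv: (kv[1], kv[0]))[0]
        modal_members = [r for r in members if len(r.sequence) == modal]
        rest = [r for r in members if len(r.sequence) != modal]
        out.append(_column_vote(modal_members))
        out.extend(rest)
    return out


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def apply_filters(
    records: Sequence,
    config: FilterConfig,
    no_overlap_count: int = 0,
) -> tuple[list, FilterReport]:
    """Apply the stop-codon / length / quality criteria to annotated reads.

    ``records`` are objects exposing ``sequence`` (merged nt), ``mean quality``
    via ``merged.mean_quality`` or a ``has_stop`` flag from annotation; reads
    that failed to merge never reach this stage and their count is forwarded
    via ``no_overlap_count``.  A record failing several criteria is counted
    once, under the first failing criterion in the order stop-codon, short,
    low-quality.
    """
    report = FilterReport(input_count=len(records) + no_overlap_count)
    report.rejected_no_overlap = no_overlap_count
    retained = []
    for rec in records:
        seq = rec.merged.sequence
        if config.reject_stop_codons and rec.has_stop:
            report.rejected_stop_codon += 1
            continue
        if len(seq) < config.min_length:
            report.rejected_short += 1
            continue
        if config.quality_aggregate == "mean":
            q = rec.merged.mean_quality
        else:
            q = min(rec.merged.quality) if rec.merged.quality else 0.0
        if q < config.min_quality:
            report.rejected_low_quality += 1
            continue
        retained.append(rec)
    report.retained_count = len(retained)
    report.check()
    return retained, report
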