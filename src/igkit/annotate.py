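"""V(D)J gene assignment, region delineation and annotation records.

The annotator aligns every germline V gene of a chain against the merged read
(a "fit" alignment: the whole germline may sit anywhere inside the read) under
match +2 / mismatch -2 / gap open -6 / gap extend -1, keeps the best-scoring
call, and repeats for J genes on the read suffix right of the V span.  The
reading frame is inferred by mapping the V gene's frame onto the read, the
junction between V and J is searched for the longest exact D-gene block, and
the CDR3 is delineated from the conserved anchor codons carried as germline
metadata (V: Cys codon; J: FR4-anchor codon).  CDR3 includes both anchor
codons.

Reads are grouped into :class:`AnnotationRecord` rows keyed by
``(chain, isotype, aa_sequence)`` — the unit all downstream statistics count.
A pre-annotated AIRR-style rearrangement TSV can be ingested instead of using
the built-in annotator (:func:`ingest_airr`), so any external annotation tool
can be substituted.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .errors import AnnotationError, InputError
from .germline import GermlineGene, GermlineSet, subgroup_of
from .preprocess import MergedRead

logger = logging.getLogger(__name__)

#: chain label mapping used in all reports
CHAIN_LABELS = {"IGH": "VH", "IGK": "Vκ", "IGL": "Vλ"}

MATCH_SCORE = 2
MISMATCH_SCORE = -2
GAP_OPEN = -6
GAP_EXTEND = -1
V_SCORE_FLOOR = 50


@dataclass
class GeneCall:
    """A germline gene assignment for one read."""

    allele_name: str
    subgroup: str
    alignment: list[tuple[int, int]]  # (read position, germline position) pairs
    mutation_count: int
    score: float

    @property
    def read_span(self) -> tuple[int, int]:
        return self.alignment[0][0], self.alignment[-1][0] + 1

    def read_position_of(self, germline_pos: int) -> int | None:
        """Read coordinate aligned to a germline coordinate, or None."""
        # alignments are short lists of matched pairs; binary search not needed
        for rp, gp in self.alignment:
            if gp == germline_pos:
                return rp
        return None


@dataclass
class RegionMap:
    """0-based half-open read offsets of the delineated regions."""

    orf_start: int
    cdr3_start: int
    cdr3_end: int
    vr_end: int  # end of the variable region (end of the J alignment, codon-trimmed)

    def regions(self) -> dict[str, tuple[int, int]]:
        return {
            "FR1-FR3": (self.orf_start, self.cdr3_start),
            "CDR3": (self.cdr3_start, self.cdr3_end),
            "FR4": (self.cdr3_end, self.vr_end),
        }


@dataclass
class AnnotatedRead:
    """A merged read together with its gene calls and translation."""

    merged: MergedRead
    chain: str  # IGH / IGK / IGL
    v_call: GeneCall
    j_call: GeneCall
    d_call: GeneCall | None
    region_map: RegionMap
    aa_sequence: str  # variable-region translation (ORF start .. FR4 end)
    full_aa: str  # translation through the end of the read (for isotype matching)
    cdr3_aa: str
    has_stop: bool
    isotype: str = "unknown"

    @property
    def chain_label(self) -> str:
        return CHAIN_LABELS[self.chain]

    @property
    def nt_sequence(self) -> str:
        """Trimmed nucleotide read: exactly the codons of ``aa_sequence``."""
        s = self.region_map.orf_start
        return self.merged.sequence[s : s + 3 * len(self.aa_sequence)]


@dataclass
class AnnotationRecord:
    """One row of the per-chain annotation table (unique AA sequences).

    Identical amino-acid sequences (within a chain and isotype) are grouped to
    a single record with their read counts summed; ``members`` retains the
    underlying nucleotide variants with their counts and original FASTQ read
    indices so amino-acid level results stay linked to the nucleotide level.
    """

    chain: str  # report label: VH / Vκ / Vλ
    isotype: str
    nt_sequence: str
    aa_sequence: str
    cdr3_aa: str
    v_subgroup: str
    d_subgroup: str
    j_subgroup: str
    count: int
    members: list[tuple[str, int, list[int]]] = field(default_factory=list)
    exemplar: AnnotatedRead | None = None

    TSV_COLUMNS = (
        "chain",
        "isotype",
        "nt_sequence",
        "aa_sequence",
        "cdr3_aa",
        "v_subgroup",
        "d_subgroup",
        "j_subgroup",
        "count",
    )

    def as_row(self) -> tuple:
        return (
            self.chain,
            self.isotype,
            self.nt_sequence,
            self.aa_sequence,
            self.cdr3_aa,
            self.v_subgroup,
            self.d_subgroup,
            self.j_subgroup,
            self.count,
        )


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _fit_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.match_score = MATCH_SCORE
    a.mismatch_score = MISMATCH_SCORE
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    # free end gaps on the read so the whole germline fits inside it
    a.end_deletion_score = 0
    return a


def _call_gene(
    aligner: Align.PairwiseAligner,
    read: str,
    gene: GermlineGene,
    read_offset: int = 0,
) -> GeneCall | None:
    if not read:
        return None
    try:
        aln = aligner.align(read, gene.sequence)[0]
    except (IndexError, ValueError):
        return None
    pairs: list[tuple[int, int]] = []
    mismatches = 0
    gap_events = 0
    prev_block_end: tuple[int, int] | None = None
    for (ts, te), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
        if prev_block_end is not None:
            gap_events += 1  # each indel event counts once regardless of length
        prev_block_end = (te, qe)
        for i in range(te - ts):
            rp, gp = ts + i, qs + i
            if read[rp] != gene.sequence[gp]:
                mismatches += 1
            pairs.append((rp + read_offset, gp))
    if not pairs:
        return None
    return GeneCall(
        allele_name=gene.allele_name,
        subgroup=gene.subgroup,
        alignment=pairs,
        mutation_count=mismatches + gap_events,
        score=float(aln.score),
    )


def _best_call(
    aligner: Align.PairwiseAligner,
    read: str,
    genes: list[GermlineGene],
    read_offset: int = 0,
) -> GeneCall | None:
    best: GeneCall | None = None
    for g in genes:
        call = _call_gene(aligner, read, g, read_offset)
        if call is None:
            continue
        if best is None or (call.score, -call.mutation_count, _neg_name(call)) > (
            best.score,
            -best.mutation_count,
            _neg_name(best),
        ):
            best = call
    return best


class _neg_name:
    """Sort helper: lexicographically smaller allele name wins a tie."""

    def __init__(self, call: GeneCall):
        self.name = call.allele_name

    def __lt__(self, other: "_neg_name") -> bool:
        return self.name > other.name

    def __gt__(self, other: "_neg_name") -> bool:
        return self.name < other.name

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_name) and self.name == other.name


def assign_v_j(
    read: MergedRead,
    germlines: GermlineSet,
    chain: str,
    score_floor: float = V_SCORE_FLOOR,
) -> tuple[GeneCall, GeneCall, int]:
    """Best V and J calls for one chain, plus the inferred ORF start offset.

    Raises :class:`AnnotationError` when the best V score is below the floor
    or no J can be placed right of the V span.
    """
    aligner = _fit_aligner()
    v_genes = germlines.select(chain, "V")
    j_genes = germlines.select(chain, "J")
    if not v_genes or not j_genes:
        raise AnnotationError(f"germline set lacks V or J genes for {chain}")
    v_call = _best_call(aligner, read.sequence, v_genes)
    if v_call is None or v_call.score < score_floor:
        raise AnnotationError(
            f"unannotatable read: best V score "
            f"{v_call.score if v_call else 'n/a'} below floor {score_floor}"
        )
    v_end = v_call.read_span[1]
    j_call = _best_call(aligner, read.sequence[v_end:], j_genes, read_offset=v_end)
    if j_call is None:
        raise AnnotationError("unannotatable read: no J alignment right of the V span")
    # reading frame: germline V genes start in frame, so the read codon phase
    # at the first aligned position equals the germline phase there
    r0, g0 = v_call.alignment[0]
    orf_start = r0 - (g0 % 3)
    while orf_start < 0:
        orf_start += 3
    return v_call, j_call, orf_start


def assign_d(
    junction_nt: str, germlines: GermlineSet, min_d_match: int = 5, chain: str = "IGH"
) -> GeneCall | None:
    """Longest exact substring match of the junction against any D gene.

    Returns ``None`` when the longest match is shorter than ``min_d_match``
    nucleotides (default 5) — short coincidental matches carry no signal.
    """
    if not junction_nt:
        return None
    best_len = 0
    best_gene: GermlineGene | None = None
    best_pos = (0, 0)  # (junction offset, germline offset)
    for gene in sorted(germlines.select(chain, "D"), key=lambda g: g.allele_name):
        n = len(gene.sequence)
        for length in range(min(n, len(junction_nt)), best_len, -1):
            found = False
            for gs in range(0, n - length + 1):
                sub = gene.sequence[gs : gs + length]
                jp = junction_nt.find(sub)
                if jp >= 0:
                    best_len, best_gene, best_pos = length, gene, (jp, gs)
                    found = True
                    break
            if found:
                break
    if best_gene is None or best_len < min_d_match:
        return None
    jp, gs = best_pos
    pairs = [(jp + i, gs + i) for i in range(best_len)]
    return GeneCall(
        allele_name=best_gene.allele_name,
        subgroup=best_gene.subgroup,
        alignment=pairs,
        mutation_count=0,
        score=float(best_len),
    )


def delineate_regions(
    read: MergedRead,
    v_call: GeneCall,
    j_call: GeneCall,
    v_anchor: int,
    j_anchor: int,
    orf_start: int,
) -> RegionMap:
    """Map the germline CDR3 anchors onto the read.

    CDR3 spans from the read position of the V gene's conserved Cys codon
    through the read position of the J gene's FR4-anchor codon inclusive
    (both anchor codons belong to the CDR3).  Raises :class:`AnnotationError`
    when either anchor is not covered by its alignment ("cdr3-undefined").
    """
    cdr3_start = v_call.read_position_of(v_anchor)
    j_anchor_read = j_call.read_position_of(j_anchor)
    if cdr3_start is None or j_anchor_read is None:
        raise AnnotationError("cdr3-undefined: anchor not covered by the alignment")
    cdr3_end = j_anchor_read + 3
    if cdr3_end > len(read.sequence) or cdr3_start >= cdr3_end:
        raise AnnotationError("cdr3-undefined: anchors map outside the read")
    if (cdr3_start - orf_start) % 3 != 0 or (cdr3_end - orf_start) % 3 != 0:
        raise AnnotationError("cdr3-undefined: anchors out of frame (indel in junction)")
    j_end = j_call.read_span[1]
    vr_end = orf_start + 3 * ((j_end - orf_start) // 3)
    return RegionMap(
        orf_start=orf_start, cdr3_start=cdr3_start, cdr3_end=cdr3_end, vr_end=vr_end
    )


# ---------------------------------------------------------------------------
# the annotator
# ---------------------------------------------------------------------------

class Annotator:
    """Annotate merged reads against a germline set.

    ``chains`` restricts the search; by default every chain present in the
    germline set is tried and the chain with the best V score wins.
    """

    def __init__(
        self,
        germlines: GermlineSet,
        chains: list[str] | None = None,
        score_floor: float = V_SCORE_FLOOR,
        min_d_match: int = 5,
    ):
        self.germlines = germlines
        self.chains = chains or germlines.chains
        self.score_floor = score_floor
        self.min_d_match = min_d_match
        self._anchors = {
            g.allele_name: g.cdr3_anchor
            for g in germlines.genes
            if g.cdr3_anchor is not None
        }
        self.failures: Counter[str] = Counter()

    def annotate(self, read: MergedRead) -> AnnotatedRead | None:
        best: tuple[float, str, GeneCall, GeneCall, int] | None = None
        for chain in self.chains:
            try:
                v_call, j_call, orf = assign_v_j(
                    read, self.germlines, chain, self.score_floor
                )
            except AnnotationError:
                continue
            if best is None or v_call.score > best[0]:
                best = (v_call.score, chain, v_call, j_call, orf)
        if best is None:
            self.failures["unannotatable"] += 1
            return None
        _, chain, v_call, j_call, orf_start = best
        try:
            region_map = delineate_regions(
                read,
                v_call,
                j_call,
                self._anchors[v_call.allele_name],
                self._anchors[j_call.allele_name],
                orf_start,
            )
        except AnnotationError:
            self.failures["cdr3_undefined"] += 1
            return None

        seq = read.sequence
        full_nt = seq[orf_start : orf_start + 3 * ((len(seq) - orf_start) // 3)]
        full_aa = str(Seq(full_nt).translate())
        n_var = (region_map.vr_end - orf_start) // 3
        aa_sequence = full_aa[:n_var]
        has_stop = "*" in aa_sequence
        cdr3_aa = full_aa[
            (region_map.cdr3_start - orf_start) // 3 : (region_map.cdr3_end - orf_start) // 3
        ]

        d_call = None
        if chain == "IGH" and self.germlines.select(chain, "D"):
            junction = seq[v_call.read_span[1] : j_call.read_span[0]]
            d_call = assign_d(junction, self.germlines, self.min_d_match, chain)

        return AnnotatedRead(
            merged=read,
            chain=chain,
            v_call=v_call,
            j_call=j_call,
            d_call=d_call,
            region_map=region_map,
            aa_sequence=aa_sequence,
            full_aa=full_aa,
            cdr3_aa=cdr3_aa,
            has_stop=has_stop,
        )


# ---------------------------------------------------------------------------
# record building
# ---------------------------------------------------------------------------

def _plurality(votes: list[tuple[str, int]]) -> str:
    """Value with the largest summed weight; ties lexicographically smaller."""
    weights: dict[str, int] = defaultdict(int)
    for value, w in votes:
        weights[value] += w
    return min(weights, key=lambda v: (-weights[v], v))


def build_annotation_records(reads: list[AnnotatedRead]) -> list[AnnotationRecord]:
    """Group annotated reads into unique-AA-sequence records.

    Grouping key is ``(chain, isotype, aa_sequence)``; counts are summed, the
    representative nucleotide sequence is the most frequent variant (ties
    lexicographic) and conflicting subgroup calls are resolved by plurality
    over read counts.
    """
    groups: dict[tuple[str, str, str], list[AnnotatedRead]] = defaultdict(list)
    for r in reads:
        groups[(r.chain_label, r.isotype, r.aa_sequence)].append(r)
    records = []
    for (chain_label, isotype, aa), members in sorted(groups.items()):
        nt_variants: dict[str, int] = defaultdict(int)
        nt_indices: dict[str, list[int]] = defaultdict(list)
        for r in members:
            nt_variants[r.nt_sequence] += r.merged.count
            nt_indices[r.nt_sequence].extend(r.merged.read_indices)
        rep_nt = min(nt_variants, key=lambda s: (-nt_variants[s], s))
        exemplar = next(r for r in members if r.nt_sequence == rep_nt)
        count = sum(r.merged.count for r in members)
        records.append(
            AnnotationRecord(
                chain=chain_label,
                isotype=isotype,
                nt_sequence=rep_nt,
                aa_sequence=aa,
                cdr3_aa=_plurality([(r.cdr3_aa, r.merged.count) for r in members]),
                v_subgroup=_plurality(
                    [(r.v_call.subgroup, r.merged.count) for r in members]
                ),
                d_subgroup=_plurality(
                    [
                        (r.d_call.subgroup if r.d_call else "none", r.merged.count)
                        for r in members
                    ]
                ),
                j_subgroup=_plurality(
                    [(r.j_call.subgroup, r.merged.count) for r in members]
                ),
                count=count,
                members=[
                    (nt, nt_variants[nt], sorted(nt_indices[nt]))
                    for nt in sorted(nt_variants, key=lambda s: (-nt_variants[s], s))
                ],
                exemplar=exemplar,
            )
        )
    return records


# ---------------------------------------------------------------------------
# AIRR ingestion
# ---------------------------------------------------------------------------

_AIRR_REQUIRED = ("sequence", "v_call", "j_call", "junction_aa")


def ingest_airr(path: str | Path) -> list[AnnotationRecord]:
    """Build annotation records from an AIRR-style rearrangement TSV.

    Required columns: ``sequence``, ``v_call``, ``j_call``, ``junction_aa``;
    ``sequence_aa`` is translated from ``sequence`` when absent, ``d_call``
    defaults to none, ``duplicate_count`` to 1 and ``isotype`` to unknown.
    Rows whose amino-acid sequence contains a stop codon are dropped and
    logged (stop-codon filter criterion).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _AIRR_REQUIRED if c not in df.columns]
    if missing:
        raise InputError(f"AIRR table missing mandatory columns: {', '.join(missing)}")

    grouped: dict[tuple[str, str, str], dict] = {}
    dropped = 0
    for _, row in df.iterrows():
        nt = (row["sequence"] or "").strip().upper()
        if "sequence_aa" in df.columns and isinstance(row.get("sequence_aa"), str):
            aa = row["sequence_aa"].strip()
        else:
            aa = str(Seq(nt[: 3 * (len(nt) // 3)]).translate())
        if not aa or "*" in aa:
            dropped += 1
            continue
        v_call = (row["v_call"] or "").split(",")[0].strip()
        j_call = (row["j_call"] or "").split(",")[0].strip()
        if not v_call or not j_call:
            dropped += 1
            continue
        d_raw = row.get("d_call") if "d_call" in df.columns else None
        d_call = d_raw.split(",")[0].strip() if isinstance(d_raw, str) and d_raw.strip() else ""
        locus = v_call[:3].upper()
        chain_label = CHAIN_LABELS.get(locus)
        if chain_label is None:
            dropped += 1
            continue
        try:
            cnt = int(float(row["duplicate_count"])) if "duplicate_count" in df.columns and str(row.get("duplicate_count")).strip() not in ("", "nan", "None") else 1
        except ValueError:
            cnt = 1
        isotype = row.get("isotype") if "isotype" in df.columns else None
        isotype = isotype.strip() if isinstance(isotype, str) and isotype.strip() else (
            "unknown" if chain_label == "VH" else "none"
        )
        junction = row["junction_aa"] if isinstance(row["junction_aa"], str) else ""
        key = (chain_label, isotype, aa)
        slot = grouped.setdefault(
            key,
            {
                "nt": Counter(),
                "cdr3": junction,
                "v": subgroup_of(v_call),
                "d": subgroup_of(d_call) if d_call else "none",
                "j": subgroup_of(j_call),
                "count": 0,
            },
        )
        slot["nt"][nt] += cnt
        slot["count"] += cnt
    if dropped:
        logger.info("ingest_airr: dropped %d rows failing record invariants", dropped)

    records = []
    for (chain_label, isotype, aa), slot in sorted(grouped.items()):
        rep_nt = min(slot["nt"], key=lambda s: (-slot["nt"][s], s))
        records.append(
            AnnotationRecord(
                chain=chain_label,
                isotype=isotype,
                nt_sequence=rep_nt,
                aa_sequence=aa,
                cdr3_aa=slot["cdr3"],
                v_subgroup=slot["v"],
                d_subgroup=slot["d"],
                j_subgroup=slot["j"],
                count=slot["count"],
                members=[(nt, c, []) for nt, c in slot["nt"].most_common()],
            )
        )
    return records
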