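"""Clonal clustering and per-clone analysis.

A clone is the set of all variable-region sequences with an identical CDRH3
amino-acid sequence (anchor residues included).  Two quantities summarize
each clone: ``y``, the number of reads associated with it (clonal expansion),
and ``x``, the number of unique amino-acid sequences within it (``x <= y``).
The report lists the K clones with the highest ``y`` (default K = 100).

For each reported clone the members are multiply aligned by the center-star
method (center = highest-count member; pairwise global alignments under
BLOSUM62 with gap open -10 / extend -1, merged by once-a-gap-always-a-gap),
a per-column plurality consensus is computed, and the member most similar to
the consensus (identities / alignment length) is reported as representative,
together with its nucleotide sequence.  A position x residue frequency matrix
(read-count weighted by default) supports sequence-logo rendering.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .annotate import AnnotationRecord

GAP = "-"

DEFAULT_TOP_K = 100


@dataclass
class Clone:
    """A CDRH3-keyed cluster of annotation records."""

    cdrh3_aa: str
    members: list[tuple[str, int, str]]  # (aa_sequence, read count, representative nt)
    consensus_aa: str = ""
    representative_aa: str = ""
    representative_nt: str = ""
    similarity: float = 0.0

    @property
    def x(self) -> int:
        return len(self.members)

    @property
    def y(self) -> int:
        return sum(c for _, c, _ in self.members)


def cluster_clones(records: list[AnnotationRecord]) -> list[Clone]:
    """Group records into clones by identical CDR3 amino-acid sequence.

    Records without a defined CDR3 are excluded.  ``x`` counts unique AA
    sequences, ``y`` sums their read counts.
    """
    groups: dict[str, list[AnnotationRecord]] = defaultdict(list)
    for rec in records:
        if rec.cdr3_aa:
            groups[rec.cdr3_aa].append(rec)
    clones = []
    for cdr3, members in sorted(groups.items()):
        clones.append(
            Clone(
                cdrh3_aa=cdr3,
                members=[(m.aa_sequence, m.count, m.nt_sequence) for m in members],
            )
        )
    return clones


def top_k_clones(clones: list[Clone], k: int = DEFAULT_TOP_K) -> list[Clone]:
    """The k clones with the highest y (ties: higher x, then CDRH3 lexicographic)."""
    return sorted(clones, key=lambda c: (-c.y, -c.x, c.cdrh3_aa))[:k]


# ---------------------------------------------------------------------------
# center-star MSA
# ---------------------------------------------------------------------------

def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -10
    a.extend_gap_score = -1
    a.mode = "global"
    return a


def _gapped_rows(aligner: Align.PairwiseAligner, center: str, other: str) -> tuple[str, str]:
    aln = aligner.align(center, other)[0]
    c_row, o_row = [], []
    pc = po = 0
    for (cs, ce), (os_, oe) in zip(aln.aligned[0], aln.aligned[1]):
        if cs > pc:
            c_row.append(center[pc:cs])
            o_row.append(GAP * (cs - pc))
        if os_ > po:
            c_row.append(GAP * (os_ - po))
            o_row.append(other[po:os_])
        c_row.append(center[cs:ce])
        o_row.append(other[os_:oe])
        pc, po = ce, oe
    if pc < len(center):
        c_row.append(center[pc:])
        o_row.append(GAP * (len(center) - pc))
    if po < len(other):
        c_row.append(GAP * (len(other) - po))
        o_row.append(other[po:])
    return "".join(c_row), "".join(o_row)


def align_clone_members(clone: Clone) -> list[str]:
    """Center-star multiple alignment of a clone's member AA sequences.

    The center is the member with the highest read count (ties: longest, then
    lexicographic); all other members are aligned pairwise to the center and
    merged under the once-a-gap-always-a-gap rule.  Row order matches
    ``clone.members``.
    """
    seqs = [aa for aa, _, _ in clone.members]
    if len(seqs) == 1:
        return [seqs[0]]
    order = sorted(
        range(len(clone.members)),
        key=lambda i: (-clone.members[i][1], -len(seqs[i]), seqs[i]),
    )
    center_idx = order[0]
    center = seqs[center_idx]
    aligner = _protein_aligner()

    # pairwise alignments to the center
    pairs = {}
    for i, s in enumerate(seqs):
        if i == center_idx:
            continue
        pairs[i] = _gapped_rows(aligner, center, s)

    # merged center coordinates: for each center residue, the max gap run
    # inserted before it by any pairwise alignment
    n = len(center)
    gaps_before = [0] * (n + 1)
    for c_row, _ in pairs.values():
        pos = 0
        run = 0
        for ch in c_row:
            if ch == GAP:
                run += 1
            else:
                gaps_before[pos] = max(gaps_before[pos], run)
                run = 0
                pos += 1
        gaps_before[n] = max(gaps_before[n], run)

    def project(c_row: str, o_row: str) -> str:
        out = []
        pos = 0
        run: list[str] = []
        for c_ch, o_ch in zip(c_row, o_row):
            if c_ch == GAP:
                run.append(o_ch)
            else:
                out.append(GAP * (gaps_before[pos] - len(run)) + "".join(run))
                out.append(o_ch)
                run = []
                pos += 1
        out.append(GAP * (gaps_before[n] - len(run)) + "".join(run))
        return "".join(out)

    rows = []
    for i in range(len(seqs)):
        if i == center_idx:
            rows.append(project(center, center))
        else:
            rows.append(project(*pairs[i]))
    width = max(len(r) for r in rows)
    assert all(len(r) == width for r in rows), "center-star merge produced ragged rows"
    return rows


def clone_consensus(msa: list[str]) -> str:
    """Per-column plurality consensus (residue ties alphabetical).

    Columns where gaps outnumber the leading residue are dropped.
    """
    if not msa:
        return ""
    out = []
    for col in zip(*msa):
        counts = Counter(col)
        gap_n = counts.pop(GAP, 0)
        if not counts:
            continue
        best = min(counts, key=lambda ch: (-counts[ch], ch))
        if gap_n > counts[best]:
            continue
        out.append(best)
    return "".join(out)


def most_similar_member(clone: Clone, consensus: str) -> tuple[str, float, str]:
    """The member closest to the consensus.

    Similarity = identical positions / alignment length in a global alignment
    against the consensus; ties go to the higher-count member, then
    lexicographic.  Returns (representative AA, similarity, representative nt).
    """
    aligner = _protein_aligner()
    best: tuple[float, int, str, str] | None = None
    for aa, count, nt in clone.members:
        if aa == consensus:
            sim = 1.0
        else:
            c_row, o_row = _gapped_rows(aligner, consensus, aa)
            ident = sum(a == b and a != GAP for a, b in zip(c_row, o_row))
            sim = ident / len(c_row) if c_row else 0.0
        cand = (sim, count, aa, nt)
        if best is None or (cand[0], cand[1], _RevStr(cand[2])) > (
            best[0],
            best[1],
            _RevStr(best[2]),
        ):
            best = cand
    assert best is not None
    return best[2], best[0], best[3]


class _RevStr:
    """Comparison helper: lexicographically smaller string ranks higher."""

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_RevStr") -> bool:
        return self.s > other.s

    def __gt__(self, other: "_RevStr") -> bool:
        return self.s < other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _RevStr) and self.s == other.s


def analyze_clone(clone: Clone) -> Clone:
    """Fill in MSA-derived fields (consensus, representative, similarity)."""
    msa = align_clone_members(clone)
    clone.consensus_aa = clone_consensus(msa)
    rep_aa, sim, rep_nt = most_similar_member(clone, clone.consensus_aa)
    clone.representative_aa = rep_aa
    clone.similarity = sim
    clone.representative_nt = rep_nt
    return clone


def sequence_logo_matrix(
    msa: list[str], weights: list[int] | None = None
) -> pd.DataFrame:
    """Position x residue frequency matrix for sequence-logo rendering.

    Frequencies are computed per MSA column over non-gap residues, weighted
    by member read counts (pass ``weights=None`` after normalizing, or a list
    of per-row weights; ``[1]*rows`` gives the unweighted variant).  Columns
    dropped by the consensus rule (gap-majority) are dropped here too.
    """
    if not msa:
        return pd.DataFrame(columns=["position", "residue", "frequency"])
    if weights is None:
        weights = [1] * len(msa)
    rows = []
    position = 0
    for col in zip(*msa):
        counts: dict[str, float] = defaultdict(float)
        gap_w = 0.0
        for ch, w in zip(col, weights):
            if ch == GAP:
                gap_w += w
            else:
                counts[ch] += w
        if not counts:
            continue
        best = min(counts, key=lambda ch: (-counts[ch], ch))
        if gap_w > counts[best]:
            continue
        total = sum(counts.values())
        for ch in sorted(counts):
            rows.append(
                {"position": position, "residue": ch, "frequency": counts[ch] / total}
            )
        position += 1
    return pd.DataFrame(rows, columns=["position", "residue", "frequency"])


def clone_table(clones: list[Clone]) -> pd.DataFrame:
    """The 7-field clone summary table."""
    rows = []
    for c in clones:
        rows.append(
            {
                "cdrh3_aa": c.cdrh3_aa,
                "y_reads": c.y,
                "x_unique_aa": c.x,
                "consensus_aa": c.consensus_aa,
                "representative_aa": c.representative_aa,
                "similarity": c.similarity,
                "representative_nt": c.representative_nt,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cdrh3_aa",
            "y_reads",
            "x_unique_aa",
            "consensus_aa",
            "representative_aa",
            "similarity",
            "representative_nt",
        ],
    )


def expansion_table(clones: list[Clone]) -> pd.DataFrame:
    """Rank / y / x table for the clonal-expansion plot."""
    ranked = top_k_clones(clones, k=len(clones))
    return pd.DataFrame(
        [
            {"rank": i + 1, "cdrh3_aa": c.cdrh3_aa, "y_reads": c.y, "x_unique_aa": c.x}
            for i, c in enumerate(ranked)
        ],
        columns=["rank", "cdrh3_aa", "y_reads", "x_unique_aa"],
    )
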