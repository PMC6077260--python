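"""Per-replicate repertoire statistics.

All distributions count one vote per unique amino-acid sequence (one
:class:`~igkit.annotate.AnnotationRecord`), not per read: subgroup usage is
explicitly defined that way in the output contract, and the CDR3-length, SHM
and isotype tables use the same unit for internal consistency.

Somatic hypermutation (SHM) is counted over the V-gene span only: mismatched
aligned positions plus one per indel event.  Mutations are stratified into
synonymous (Ks) and non-synonymous (Ka) by comparing each fully aligned codon
of the read against its germline codon and translating both; counts are
normalized per compared codon, so ``ka + ks <= 1`` always holds.  The ratio
Ka/Ks is reported only when Ks > 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .annotate import AnnotatedRead, AnnotationRecord, GeneCall
from .germline import GermlineSet


@dataclass
class MutationProfile:
    """Per-record V-gene mutation summary."""

    total_mutations: int
    ka_per_codon: float
    ks_per_codon: float
    codons_compared: int

    @property
    def ka_ks_ratio(self) -> float | None:
        if self.ks_per_codon > 0:
            return self.ka_per_codon / self.ks_per_codon
        return None


def usage_table(votes: Counter) -> pd.DataFrame:
    """Label -> (count, frequency) table; frequencies sum to 1 when non-empty."""
    total = sum(votes.values())
    rows = [
        {"label": label, "count": n, "frequency": n / total}
        for label, n in sorted(votes.items(), key=lambda kv: (-kv[1], str(kv[0])))
    ]
    return pd.DataFrame(rows, columns=["label", "count", "frequency"])


def count_shm(v_call: GeneCall) -> int:
    """Number of mutations vs the germline V gene (indels count one per event)."""
    return v_call.mutation_count


def ka_ks(read_seq: str, v_call: GeneCall, germline_v: str, orf_start: int) -> MutationProfile:
    """Classify V-gene mutations as synonymous/non-synonymous per codon.

    Each germline codon whose three positions are aligned to three consecutive,
    codon-aligned read positions is compared; codons disrupted by indels are
    excluded.  A changed codon counts once, as non-synonymous when the
    translations differ, else synonymous.
    """
    pos_map = dict((gp, rp) for rp, gp in v_call.alignment)
    n_codons = len(germline_v) // 3
    compared = 0
    ka = 0
    ks = 0
    for c in range(n_codons):
        g0 = 3 * c
        rps = [pos_map.get(g0 + i) for i in range(3)]
        if None in rps:
            continue
        if rps[1] != rps[0] + 1 or rps[2] != rps[0] + 2:
            continue  # indel inside the codon
        if (rps[0] - orf_start) % 3 != 0:
            continue  # frame shifted relative to the read ORF
        g_codon = germline_v[g0 : g0 + 3]
        r_codon = read_seq[rps[0] : rps[0] + 3]
        compared += 1
        if g_codon == r_codon:
            continue
        if str(Seq(g_codon).translate()) == str(Seq(r_codon).translate()):
            ks += 1
        else:
            ka += 1
    if compared == 0:
        return MutationProfile(v_call.mutation_count, 0.0, 0.0, 0)
    return MutationProfile(
        total_mutations=v_call.mutation_count,
        ka_per_codon=ka / compared,
        ks_per_codon=ks / compared,
        codons_compared=compared,
    )


def mutation_profiles(
    records: list[AnnotationRecord], germlines: GermlineSet
) -> pd.DataFrame:
    """SHM and Ka/Ks per unique AA sequence (records without an exemplar skipped)."""
    v_seqs = {g.allele_name: g.sequence for g in germlines.genes if g.gene_class == "V"}
    rows = []
    for rec in records:
        r = rec.exemplar
        if r is None:
            continue
        profile = ka_ks(
            r.merged.sequence, r.v_call, v_seqs[r.v_call.allele_name], r.region_map.orf_start
        )
        rows.append(
            {
                "aa_sequence": rec.aa_sequence,
                "total_mutations": profile.total_mutations,
                "ka_per_codon": profile.ka_per_codon,
                "ks_per_codon": profile.ks_per_codon,
                "ka_ks_ratio": profile.ka_ks_ratio,
                "codons_compared": profile.codons_compared,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "aa_sequence",
            "total_mutations",
            "ka_per_codon",
            "ks_per_codon",
            "ka_ks_ratio",
            "codons_compared",
        ],
    )


def shm_histogram(records: list[AnnotationRecord]) -> pd.DataFrame:
    """Frequency of V-gene mutation counts over unique AA sequences."""
    votes = Counter(
        rec.exemplar.v_call.mutation_count for rec in records if rec.exemplar is not None
    )
    return usage_table(votes)


def cdr3_length_distribution(records: list[AnnotationRecord]) -> pd.DataFrame:
    """Distribution of CDR3 amino-acid lengths."""
    votes = Counter(len(rec.cdr3_aa) for rec in records if rec.cdr3_aa)
    return usage_table(votes)


def subgroup_usage(records: list[AnnotationRecord], gene_class: str) -> pd.DataFrame:
    """Frequency of unique AA sequences per V/D/J family subgroup."""
    attr = {"V": "v_subgroup", "D": "d_subgroup", "J": "j_subgroup"}[gene_class]
    votes = Counter(
        getattr(rec, attr) for rec in records if getattr(rec, attr) not in ("", "none")
    )
    return usage_table(votes)


def vdj_combination_usage(
    records: list[AnnotationRecord], include_d: bool = False
) -> pd.DataFrame:
    """Frequencies of V-J subgroup combinations (or V-D-J triples)."""
    if include_d:
        votes = Counter(
            (rec.v_subgroup, rec.d_subgroup or "none", rec.j_subgroup) for rec in records
        )
        labels = Counter({"|".join(k): v for k, v in votes.items()})
    else:
        labels = Counter(f"{rec.v_subgroup}|{rec.j_subgroup}" for rec in records)
    return usage_table(labels)


def isotype_distribution(records: list[AnnotationRecord]) -> pd.DataFrame:
    """Isotype frequencies over unique AA sequences ("unknown" is its own slice)."""
    votes = Counter(rec.isotype for rec in records if rec.isotype != "none")
    return usage_table(votes)
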