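"""MS-ready database export.

Proteomic identification of serum/secreted antibodies searches LC-MS/MS
spectra against a personal variable-region protein database.  Tryptic
digestion requires a cleavage site (K/R) at the C terminus of the variable
region, so each heavy-chain sequence is truncated at the end of its FR4
anchor motif and a cleavage suffix is appended: ``ASTK`` for human, ``AK``
for mouse by default, optionally overridden per isotype.  Truncation before
suffixing replaces the constant-region fingerprint residues rather than
extending them (``keep_constant_tail=True`` appends to the untruncated
sequence instead).

A companion mapping file links every amino-acid sequence in the database back
to its supporting nucleotide sequences and their original FASTQ read indices,
so MS hits can be traced to individual reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .annotate import AnnotationRecord
from .isotype import BUILTIN_TABLES, IsotypeTable, locate_fr4_anchor

logger = logging.getLogger(__name__)

DEFAULT_SUFFIXES = {"human": "ASTK", "mouse": "AK"}


@dataclass
class CleavageRule:
    """Cleavage-suffix policy: a default peptide plus per-isotype overrides."""

    species: str
    default_suffix: str | None = None
    isotype_suffixes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.default_suffix is None:
            self.default_suffix = DEFAULT_SUFFIXES.get(self.species, "ASTK")

    def suffix_for(self, isotype: str) -> str:
        return self.isotype_suffixes.get(isotype, self.default_suffix)


def append_cleavage_suffix(
    records: list[AnnotationRecord],
    rule: CleavageRule,
    table: IsotypeTable | None = None,
    keep_constant_tail: bool = False,
) -> list[tuple[AnnotationRecord, str]]:
    """Suffixed (record, ms_ready_aa) pairs for heavy-chain records.

    Sequences are truncated at the FR4 anchor end, then the per-isotype (or
    default) suffix is appended.  Records whose FR4 anchor cannot be located
    are emitted unmodified with a warning.
    """
    if table is None:
        table = BUILTIN_TABLES[rule.species]
    out = []
    for rec in records:
        end = locate_fr4_anchor(rec.aa_sequence, table)
        if end is None:
            logger.warning(
                "no FR4 anchor in %s...; sequence emitted unsuffixed",
                rec.aa_sequence[:20],
            )
            out.append((rec, rec.aa_sequence))
            continue
        prefix = rec.aa_sequence if keep_constant_tail else rec.aa_sequence[:end]
        out.append((rec, prefix + rule.suffix_for(rec.isotype)))
    return out


def write_ms_fasta(
    suffixed: list[tuple[AnnotationRecord, str]], path: str | Path
) -> None:
    """Write the MS-ready FASTA (header mirrors the per-chain export headers)."""
    with open(path, "w") as fh:
        for rec, aa in suffixed:
            header = (
                f"{rec.chain}|{rec.isotype}|cdr3={rec.cdr3_aa}|v={rec.v_subgroup}"
                f"|d={rec.d_subgroup}|j={rec.j_subgroup}|counts={rec.count}"
            )
            fh.write(f">{header}\n{aa}\n")


def aa_to_dna_map(records: list[AnnotationRecord], path: str | Path) -> None:
    """Write the AA -> DNA mapping file.

    FASTA-like layout: each header is the variable-region amino-acid sequence
    itself; each following line is one supporting nucleotide variant, tab-
    separated from the comma-joined 0-based indices of the FASTQ reads that
    produced it.  Every retained read index appears exactly once in the file.
    """
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.aa_sequence}\n")
            for nt, count, indices in rec.members:
                idx = ",".join(map(str, indices)) if indices else ""
                fh.write(f"{nt}\t{idx}\n")


def read_aa_to_dna_map(path: str | Path) -> dict[str, list[tuple[str, list[int]]]]:
    """Parse an AA -> DNA mapping file back into a dict (inverse of writer)."""
    out: dict[str, list[tuple[str, list[int]]]] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:]
                out[current] = []
            else:
                nt, _, idx = line.partition("\t")
                indices = [int(i) for i in idx.split(",") if i]
                out[current].append((nt, indices))
    return out
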