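"""Germline V/D/J reference sets.

A germline set holds the reference V, D and J gene segments against which
reads are annotated.  References are stored as plain FASTA with pipe-delimited
header metadata so a set is fully self-contained::

    >IGHV1-69*01|V|IGH|IGHV1|288
    CAGGTGCAGCTGGTG...

Fields are ``allele_name|gene_class|chain|subgroup[|cdr3_anchor]``.  The
``cdr3_anchor`` is the 0-based offset of the conserved CDR3-boundary codon
within the gene: for V genes the first nucleotide of the conserved Cys codon,
for J genes the first nucleotide of the FR4-anchor (J-Trp/Phe) codon.  It is
mandatory for V and J genes so that CDR3 delineation never has to guess motifs
inside germline sequences.  All coordinates are 0-based, half-open.

Users may extend a base set with provisional novel alleles via
:func:`merge_novel_alleles`; novel entries sharing an allele name replace the
base entry (and the replacement is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import GermlineError

logger = logging.getLogger(__name__)

GENE_CLASSES = ("V", "D", "J")
CHAINS = ("IGH", "IGK", "IGL")
SPECIES = ("human", "mouse")

_NT_ALPHABET = set("ACGT")


def subgroup_of(allele_name: str) -> str:
    """Family-level subgroup of an allele name.

    The text before the first ``-`` (e.g. ``IGHV1-69*01`` -> ``IGHV1``); if no
    ``-`` is present, the text before the first ``*`` (``IGHJ4*02`` ->
    ``IGHJ4``); otherwise the full name.
    """
    if not allele_name:
        raise GermlineError("empty allele name has no subgroup")
    if "-" in allele_name:
        return allele_name.split("-", 1)[0]
    if "*" in allele_name:
        return allele_name.split("*", 1)[0]
    return allele_name


@dataclass(frozen=True)
class GermlineGene:
    """A single germline V, D or J gene segment."""

    allele_name: str
    gene_class: str
    chain: str
    sequence: str
    subgroup: str
    cdr3_anchor: int | None = None

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise GermlineError(
                f"{self.allele_name}: gene_class must be one of {GENE_CLASSES}, "
                f"got {self.gene_class!r}"
            )
        if self.chain not in CHAINS:
            raise GermlineError(
                f"{self.allele_name}: chain must be one of {CHAINS}, got {self.chain!r}"
            )
        if not self.sequence:
            raise GermlineError(f"{self.allele_name}: empty sequence")
        bad = set(self.sequence) - _NT_ALPHABET
        if bad:
            raise GermlineError(
                f"{self.allele_name}: invalid nucleotides {sorted(bad)} in sequence"
            )
        if not self.subgroup:
            raise GermlineError(f"{self.allele_name}: empty subgroup")
        if self.gene_class in ("V", "J"):
            if self.cdr3_anchor is None:
                raise GermlineError(
                    f"{self.allele_name}: {self.gene_class} gene requires a cdr3_anchor"
                )
            if self.cdr3_anchor % 3 != 0:
                raise GermlineError(
                    f"{self.allele_name}: cdr3_anchor {self.cdr3_anchor} is not a "
                    "multiple of 3 from the reading-frame start"
                )
            if not 0 <= self.cdr3_anchor < len(self.sequence):
                raise GermlineError(
                    f"{self.allele_name}: cdr3_anchor {self.cdr3_anchor} outside "
                    f"sequence of length {len(self.sequence)}"
                )


@dataclass
class GermlineSet:
    """A validated collection of germline genes for one species."""

    species: str
    genes: list[GermlineGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise GermlineError(f"species must be one of {SPECIES}, got {self.species!r}")
        self.validate()

    # -- access -----------------------------------------------------------
    def select(self, chain: str, gene_class: str) -> list[GermlineGene]:
        return [g for g in self.genes if g.chain == chain and g.gene_class == gene_class]

    @property
    def chains(self) -> list[str]:
        return sorted({g.chain for g in self.genes})

    def __len__(self) -> int:
        return len(self.genes)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.allele_name in seen:
                raise GermlineError(f"duplicate allele name {g.allele_name!r}")
            seen.add(g.allele_name)
        for chain in self.chains:
            for cls in ("V", "J"):
                if not self.select(chain, cls):
                    raise GermlineError(f"no {cls} genes for {chain}")


def _parse_header(header: str) -> tuple[str, str, str, str, int | None]:
    parts = header.split("|")
    if len(parts) not in (4, 5):
        raise GermlineError(
            f"malformed germline header {header!r}: expected "
            "allele_name|gene_class|chain|subgroup[|cdr3_anchor]"
        )
    allele, cls, chain, subgroup = (p.strip() for p in parts[:4])
    anchor: int | None = None
    if len(parts) == 5 and parts[4].strip():
        try:
            anchor = int(parts[4])
        except ValueError as exc:
            raise GermlineError(
                f"malformed cdr3_anchor {parts[4]!r} in header {header!r}"
            ) from exc
    return allele, cls, chain, subgroup, anchor


def load_germline_set(path: str | Path, species: str) -> GermlineSet:
    """Load and validate a germline set from a metadata-bearing FASTA file."""
    path = Path(path)
    if not path.exists():
        raise InputFileMissing(path)
    genes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        allele, cls, chain, subgroup, anchor = _parse_header(rec.description)
        genes.append(
            GermlineGene(
                allele_name=allele,
                gene_class=cls,
                chain=chain,
                sequence=str(rec.seq).upper(),
                subgroup=subgroup,
                cdr3_anchor=anchor,
            )
        )
    if not genes:
        raise GermlineError(f"no germline records in {path}")
    return GermlineSet(species=species, genes=genes)


def write_germline_set(gset: GermlineSet, path: str | Path) -> None:
    """Serialize a germline set back to metadata-bearing FASTA (inverse of load)."""
    records = []
    for g in gset.genes:
        header = f"{g.allele_name}|{g.gene_class}|{g.chain}|{g.subgroup}"
        if g.cdr3_anchor is not None:
            header += f"|{g.cdr3_anchor}"
        records.append(SeqRecord(Seq(g.sequence), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


def merge_novel_alleles(base: GermlineSet, extra: GermlineSet) -> GermlineSet:
    """Append provisional novel alleles to a base set.

    Extras sharing an allele name with a base entry replace it; replacements
    are logged so the provenance of every annotation stays visible.
    """
    if base.species != extra.species:
        raise GermlineError(
            f"species mismatch: base is {base.species}, extra is {extra.species}"
        )
    by_name = {g.allele_name: g for g in base.genes}
    for g in extra.genes:
        if g.allele_name in by_name:
            logger.warning("novel allele %s replaces base germline entry", g.allele_name)
        by_name[g.allele_name] = g
    return GermlineSet(species=base.species, genes=list(by_name.values()))


class InputFileMissing(GermlineError):
    def __init__(self, path: Path):
        super().__init__(f"germline file not found: {path}")
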