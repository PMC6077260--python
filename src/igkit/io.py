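"""FASTQ input and tabular/FASTA output helpers."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .annotate import AnnotationRecord
from .errors import InputError
from .preprocess import ReadPair


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    """Stream mate pairs from two Phred+33 FASTQ files.

    Mates are matched positionally (the universal convention for paired
    FASTQ); a length mismatch between the files is an error.
    """
    r1_path, r2_path = Path(r1_path), Path(r2_path)
    for p in (r1_path, r2_path):
        if not p.exists():
            raise InputError(f"FASTQ file not found: {p}")
    with open(r1_path) as f1, open(r2_path) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        index = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise InputError(
                    f"paired FASTQ files {r1_path.name}/{r2_path.name} differ in length"
                )
            _, seq1, qual1 = rec1
            _, seq2, qual2 = rec2
            yield ReadPair(
                read_index=index,
                fwd_seq=seq1.upper(),
                rev_seq=seq2.upper(),
                fwd_qual=tuple(ord(c) - 33 for c in qual1),
                rev_qual=tuple(ord(c) - 33 for c in qual2),
            )
            index += 1


def write_annotation_tsv(records: list[AnnotationRecord], path: str | Path) -> None:
    """The per-chain annotation table: exactly the 9 report columns, in order."""
    df = pd.DataFrame(
        [rec.as_row() for rec in records], columns=AnnotationRecord.TSV_COLUMNS
    )
    df.to_csv(path, sep="\t", index=False)


def write_chain_fasta(records: list[AnnotationRecord], path: str | Path) -> None:
    """Per-chain AA FASTA; the header carries the record metadata."""
    with open(path, "w") as fh:
        for rec in records:
            header = (
                f"{rec.chain}|{rec.isotype}|cdr3={rec.cdr3_aa}|v={rec.v_subgroup}"
                f"|d={rec.d_subgroup}|j={rec.j_subgroup}|counts={rec.count}"
            )
            fh.write(f">{header}\n{rec.aa_sequence}\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(paths: list[Path], manifest_path: Path, flags: dict[str, str] | None = None) -> None:
    """List every artifact with its checksum (and an optional status flag)."""
    flags = flags or {}
    rows = []
    for p in sorted(paths):
        rows.append(
            {
                "file": p.name,
                "bytes": p.stat().st_size,
                "sha256": sha256_of(p),
                "status": flags.get(p.name, "ok" if p.stat().st_size else "empty-with-warning"),
            }
        )
    pd.DataFrame(rows, columns=["file", "bytes", "sha256", "status"]).to_csv(
        manifest_path, sep="\t", index=False
    )
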