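"""Multi-replicate ("joint") analysis.

Sequencing the same library in 2-6 replicates separates reproducible
molecules from preparation/sequencing artifacts: a variable region observed
in several replicates is unlikely to be an error.  This module aggregates the
per-replicate annotation records into a joint repertoire keyed by
``(chain, isotype, aa_sequence)``, carrying a per-replicate count vector for
every record, and derives:

* pairwise Pearson correlation between replicate count profiles (over the
  union with zero-fill by default, or restricted to co-occurring records);
* Venn region counts: for every non-empty subset of replicates, the number of
  unique AA sequences present in exactly that subset;
* a joint FASTA whose headers carry total and per-replicate counts.

All per-replicate statistics and the clonal analysis can be re-run on the
joint records using the total count as the record count.
"""

from __future__ import annotations

import copy
import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .annotate import AnnotationRecord
from .errors import InputError

logger = logging.getLogger(__name__)

MAX_REPLICATES = 6


@dataclass
class JointRepertoire:
    """Aggregated records with per-replicate count vectors."""

    n_replicates: int
    records: list[AnnotationRecord]
    per_replicate_counts: list[list[int]]  # parallel to records

    def __post_init__(self) -> None:
        assert len(self.records) == len(self.per_replicate_counts)
        for vec in self.per_replicate_counts:
            assert len(vec) == self.n_replicates and sum(vec) >= 1

    def project(self, i: int) -> list[AnnotationRecord]:
        """The records of replicate ``i`` with that replicate's counts."""
        out = []
        for rec, vec in zip(self.records, self.per_replicate_counts):
            if vec[i] > 0:
                r = copy.copy(rec)
                r.count = vec[i]
                out.append(r)
        return out


def _key(rec: AnnotationRecord) -> tuple[str, str, str]:
    return (rec.chain, rec.isotype, rec.aa_sequence)


def aggregate_replicates(replicates: list[list[AnnotationRecord]]) -> JointRepertoire:
    """Aggregate 1-6 replicates' record lists into a joint repertoire.

    More than six replicates are refused.  With a single replicate the joint
    structure is still built (callers suppress joint-only outputs).
    """
    n = len(replicates)
    if n == 0:
        raise InputError("no replicates to aggregate")
    if n > MAX_REPLICATES:
        raise InputError(f"too many replicates: {n} > {MAX_REPLICATES}")
    merged: dict[tuple[str, str, str], tuple[AnnotationRecord, list[int]]] = {}
    for i, records in enumerate(replicates):
        for rec in records:
            key = _key(rec)
            if key not in merged:
                joint_rec = copy.copy(rec)
                joint_rec.members = list(rec.members)
                merged[key] = (joint_rec, [0] * n)
            entry = merged[key]
            entry[1][i] += rec.count
            if entry[0] is not rec:
                entry[0].members = entry[0].members + rec.members
    records = []
    vectors = []
    for key in sorted(merged):
        rec, vec = merged[key]
        rec.count = sum(vec)
        records.append(rec)
        vectors.append(vec)
    return JointRepertoire(n_replicates=n, records=records, per_replicate_counts=vectors)


def pairwise_correlation(
    joint: JointRepertoire,
    i: int,
    j: int,
    mode: str = "union",
    values: str = "counts",
) -> float | None:
    """Pearson r between the count profiles of replicates ``i`` and ``j``.

    ``mode="union"`` zero-fills records absent from one replicate (default);
    ``mode="intersection"`` restricts to co-occurring records.  With
    ``values="frequencies"`` counts are normalized to within-replicate
    fractions first.  Returns ``None`` (explicitly, never silently 0) when
    either margin has no variance or fewer than two points remain.
    """
    if mode not in ("union", "intersection"):
        raise InputError(f"invalid correlation mode {mode!r}")
    xs, ys = [], []
    for vec in joint.per_replicate_counts:
        a, b = vec[i], vec[j]
        if mode == "intersection" and (a == 0 or b == 0):
            continue
        xs.append(a)
        ys.append(b)
    if len(xs) < 2:
        return None
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if values == "frequencies":
        if x.sum() == 0 or y.sum() == 0:
            return None
        x = x / x.sum()
        y = y / y.sum()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(sps.pearsonr(x, y).statistic)


def correlation_matrix(
    joint: JointRepertoire, mode: str = "union", values: str = "counts"
) -> np.ndarray:
    """Symmetric matrix of pairwise Pearson r (NaN where undefined)."""
    n = joint.n_replicates
    mat = np.full((n, n), np.nan)
    for i in range(n):
        mat[i, i] = 1.0
        for j in range(i + 1, n):
            r = pairwise_correlation(joint, i, j, mode=mode, values=values)
            if r is not None:
                mat[i, j] = mat[j, i] = r
    return mat


def venn_counts(joint: JointRepertoire) -> dict[tuple[int, ...], int]:
    """Unique-AA-sequence counts for every exact replicate subset.

    Keys are sorted tuples of replicate indices; the values partition the
    union of all records (each record counted under exactly the subset of
    replicates it occurs in).
    """
    counts: dict[tuple[int, ...], int] = {
        subset: 0
        for r in range(1, joint.n_replicates + 1)
        for subset in itertools.combinations(range(joint.n_replicates), r)
    }
    for vec in joint.per_replicate_counts:
        subset = tuple(i for i, c in enumerate(vec) if c > 0)
        counts[subset] += 1
    return counts


def joint_fasta(joint: JointRepertoire, path: str | Path) -> None:
    """Write the joint repertoire as FASTA with per-replicate counts.

    Header format (pipe-delimited, parseable by :func:`read_joint_fasta`)::

        >VH|IgG|cdr3=...|v=IGHV1|d=IGHD2|j=IGHJ4|counts=5|by_replicate=3,0,2
    """
    path = Path(path)
    if not joint.records:
        logger.warning("joint repertoire is empty; writing empty FASTA %s", path)
    with open(path, "w") as fh:
        for rec, vec in zip(joint.records, joint.per_replicate_counts):
            header = (
                f"{rec.chain}|{rec.isotype}|cdr3={rec.cdr3_aa}|v={rec.v_subgroup}"
                f"|d={rec.d_subgroup}|j={rec.j_subgroup}|counts={rec.count}"
                f"|by_replicate={','.join(map(str, vec))}"
            )
            fh.write(f">{header}\n{rec.aa_sequence}\n")


def read_joint_fasta(path: str | Path) -> list[tuple[dict, str]]:
    """Parse a joint FASTA back into (header fields, AA sequence) pairs."""
    out = []
    header: dict | None = None
    seq_parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    out.append((header, "".join(seq_parts)))
                parts = line[1:].split("|")
                fields: dict = {"chain": parts[0], "isotype": parts[1]}
                for p in parts[2:]:
                    k, _, v = p.partition("=")
                    fields[k] = v
                fields["counts"] = int(fields["counts"])
                fields["by_replicate"] = [
                    int(c) for c in fields["by_replicate"].split(",")
                ]
                header = fields
                seq_parts = []
            elif line:
                seq_parts.append(line)
    if header is not None:
        out.append((header, "".join(seq_parts)))
    return out
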