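"""Isotype assignment by fingerprint-peptide matching after the FR4 anchor.

The antibody class (IgM, IgD, IgG, IgA(1/2), IgE) is determined by the first
residues of the CH1 constant region, which immediately follow the conserved
framework-4 terminal motif of the variable region.  The end of FR4 is located
by the anchor peptide ``VTVSS`` in human (``VTVSS``/``LTVSS``/``VTVSA`` in
mouse); the translated read downstream of the rightmost anchor occurrence is
then matched against per-isotype fingerprint peptides:

========  ===================  ========
isotype   human                mouse
========  ===================  ========
M         GSASAPT              ESQSFP
D         APTKAP               GDKKEP
G         ASTKGPS              AKTTAP / AKTTPP
A         ASPTSP               ESARNP
A1        ASPTSPKVFPLSLCSTQP   --
A2        ASPTSPKVFPLSLDSTPQ   --
E         ASTQSP               ASIRNP
========  ===================  ========

An exact prefix match assigns directly; otherwise the closest fingerprint by
Hamming distance over the equal-length prefix is taken when the unique
minimum distance is at most one mismatch — anything farther (or a tie between
isotypes) is "unknown".  Human IgA subclasses share the short ``ASPTSP``
fingerprint and are discriminated by the long A1/A2 fingerprints; when the
read is too short to reach the discriminating tail, the assignment falls back
to plain "IgA".

Isotypes apply to heavy chains only; light-chain records carry "none".
Tables are editable: users can load their own anchors/fingerprints from a
YAML config to extend species coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InputError

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

UNKNOWN = "unknown"


@dataclass
class IsotypeTable:
    """FR4 anchor peptides and per-isotype fingerprint peptides."""

    species: str
    anchors: list[str]
    fingerprints: dict[str, list[str]]  # isotype key (e.g. "M") -> peptides

    def __post_init__(self) -> None:
        for a in self.anchors:
            if len(a) != 5 or set(a) - _AA_ALPHABET:
                raise InputError(f"invalid FR4 anchor peptide {a!r}")
        for label, peps in self.fingerprints.items():
            for p in peps:
                if not p or set(p) - _AA_ALPHABET:
                    raise InputError(f"invalid fingerprint {p!r} for isotype {label}")

    @property
    def labels(self) -> list[str]:
        return ["Ig" + k for k in self.fingerprints]


HUMAN_TABLE = IsotypeTable(
    species="human",
    anchors=["VTVSS"],
    fingerprints={
        "M": ["GSASAPT"],
        "D": ["APTKAP"],
        "G": ["ASTKGPS"],
        "A": ["ASPTSP"],
        "A1": ["ASPTSPKVFPLSLCSTQP"],
        "A2": ["ASPTSPKVFPLSLDSTPQ"],
        "E": ["ASTQSP"],
    },
)

MOUSE_TABLE = IsotypeTable(
    species="mouse",
    anchors=["VTVSS", "LTVSS", "VTVSA"],
    # the murine IgG fingerprint has two variants at its fifth position
    fingerprints={
        "M": ["ESQSFP"],
        "D": ["GDKKEP"],
        "G": ["AKTTAP", "AKTTPP"],
        "A": ["ESARNP"],
        "E": ["ASIRNP"],
    },
)

BUILTIN_TABLES = {"human": HUMAN_TABLE, "mouse": MOUSE_TABLE}


def load_isotype_table(path: str | Path) -> IsotypeTable:
    """Load an isotype table from a YAML config.

    Expected layout::

        species: human
        anchors: [VTVSS]
        fingerprints:
          M: [GSASAPT]
          G: [ASTKGPS]
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        return IsotypeTable(
            species=data["species"],
            anchors=[str(a).upper() for a in data["anchors"]],
            fingerprints={
                str(k): [str(p).upper() for p in (v if isinstance(v, list) else [v])]
                for k, v in data["fingerprints"].items()
            },
        )
    except (KeyError, TypeError) as exc:
        raise InputError(f"malformed isotype table config {path}: {exc}") from exc


def locate_fr4_anchor(aa_sequence: str, table: IsotypeTable) -> int | None:
    """End offset (exclusive) of the rightmost FR4 anchor occurrence.

    The rightmost occurrence is used: germline FR1-FR3 cannot contain FR4
    anchors, but hypermutation could create a spurious earlier copy.
    """
    best = -1
    for anchor in table.anchors:
        pos = aa_sequence.rfind(anchor)
        if pos >= 0:
            best = max(best, pos + len(anchor))
    return best if best >= 0 else None


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def assign_isotype(
    aa_sequence: str, table: IsotypeTable, max_mismatch: int = 1
) -> str:
    """Assign an isotype label from the translated read.

    The fingerprint region ``T`` is the sub-sequence following the rightmost
    FR4 anchor.  Exact prefix matches win outright; otherwise the isotype with
    the unique minimum Hamming distance (over the equal-length prefix of
    ``T``) is assigned when that distance is <= ``max_mismatch``; ties between
    isotypes and larger distances give "unknown".
    """
    end = locate_fr4_anchor(aa_sequence, table)
    if end is None:
        return UNKNOWN
    tail = aa_sequence[end:]
    if not tail:
        return UNKNOWN

    # base fingerprints exclude the long human A1/A2 extensions, which are
    # only consulted to refine an A assignment
    base = {k: v for k, v in table.fingerprints.items() if k not in ("A1", "A2")}

    def isotype_distance(peptides: list[str]) -> int:
        dists = []
        for p in peptides:
            # compare over the available prefix when the read is short
            probe = tail[: len(p)]
            dists.append(_hamming(p[: len(probe)], probe))
        return min(dists)

    dists = {k: isotype_distance(peps) for k, peps in base.items()}
    dmin = min(dists.values())
    winners = [k for k, d in dists.items() if d == dmin]
    if dmin > max_mismatch or len(winners) > 1:
        return UNKNOWN
    label = winners[0]

    if label == "A" and "A1" in table.fingerprints:
        long_a1 = table.fingerprints["A1"][0]
        long_a2 = table.fingerprints["A2"][0]
        if len(tail) >= len(long_a1):
            d1 = _hamming(long_a1, tail[: len(long_a1)])
            d2 = _hamming(long_a2, tail[: len(long_a2)])
            if d1 < d2 and d1 <= max_mismatch:
                return "IgA1"
            if d2 < d1 and d2 <= max_mismatch:
                return "IgA2"
        # discriminating tail missing or ambiguous
        return "IgA"

    return "Ig" + label
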