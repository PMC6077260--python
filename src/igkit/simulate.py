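"""Synthetic germline sets, repertoires and paired-end FASTQ with ground truth.

The simulator builds everything the pipeline consumes, so every stage is
testable without reference downloads:

* germline sets: random in-frame V genes ending in the conserved Cys codon
  (plus two codons reaching into CDR3), J genes carrying a species-matched
  FR4 anchor motif, and short D segments — all with CDR3-anchor metadata in
  their FASTA headers;
* repertoires: clones drawn from a power-law size distribution, each a
  V + junction(+D) + J recombination followed by a constant-region stub that
  begins with the isotype fingerprint peptide; per-read somatic hypermutation
  as Poisson-distributed substitutions within the V gene (stop codons are
  avoided by resampling);
* paired-end reads: forward = 5' UMI + amplicon prefix, reverse = reverse
  complement of the amplicon suffix, with per-base sequencing errors at a
  configurable rate and a two-tier quality model (Q35 baseline, Q12 at error
  sites), emulating 2 x 250 bp overlapping paired-end sequencing.

Every emitted read has exactly one ground-truth row (clone, alleles, SHM
positions, CDR3, isotype, UMI, replicate), and all randomness flows through
one seeded generator, so outputs are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .germline import GermlineGene, GermlineSet, write_germline_set
from .isotype import BUILTIN_TABLES
from .preprocess import reverse_complement

# deterministic AA -> codon encoding used when building J/constant stubs
CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAG", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

STOP_CODONS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"

# FR4 peptide downstream of the J anchor codon; ends in the species anchor motif
FR4_TAIL = {"human": "GQGTLVTVSS", "mouse": "GQGTLVTVSA"}
# J anchor residue (the conserved J-Trp) and two CDR3-tail codons ahead of it
J_CDR3_TAIL_AA = "FD"


def encode_aa(aa: str) -> str:
    return "".join(CODON_OF[c] for c in aa)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data generator.

    Defaults emulate a 2 x 250 bp overlapping paired-end amplicon run on a
    modestly diverse heavy-chain repertoire: a handful of germline segments
    per class, power-law clone sizes, Poisson SHM with mean 4 substitutions
    per read, and a 0.2% per-base sequencing error rate.
    """

    seed: int = 0
    species: str = "human"
    n_v: int = 5
    n_d: int = 4
    n_j: int = 3
    n_clones: int = 30
    clone_sizes: list[int] | None = None  # explicit per-clone reads; overrides the law
    clone_size_exponent: float = 1.5  # power-law exponent for clone sizes
    n_reads: int = 2000  # reads per replicate
    shm_rate: float = 4.0  # Poisson mean substitutions per read (V gene)
    seq_error_rate: float = 0.002  # per-base sequencing error probability
    read_length: int = 250
    umi_length: int = 0  # 0 disables UMIs
    reads_per_molecule: int = 1  # FASTQ copies per UMI-tagged molecule
    isotype_mix: dict[str, float] = dc_field(
        default_factory=lambda: {"IgM": 0.3, "IgG": 0.5, "IgA1": 0.15, "IgE": 0.05}
    )
    n_replicates: int = 1
    replicate_overlap_frac: float = 0.5  # fraction of clones shared by all replicates

    def __post_init__(self) -> None:
        if self.species not in ("human", "mouse"):
            raise InputError(f"unsupported species {self.species!r}")
        total = sum(self.isotype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError("isotype_mix probabilities must sum to 1")
        for v in self.isotype_mix.values():
            if not 0 <= v <= 1:
                raise InputError("isotype_mix probabilities must be within [0, 1]")
        if not 1 <= self.n_replicates <= 6:
            raise InputError("n_replicates must be within 1..6")
        for name in ("n_v", "n_j", "n_clones", "n_reads", "read_length"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")


@dataclass
class SimulatedRead:
    """One emitted read with its complete ground truth."""

    replicate: int
    read_index: int
    amplicon: str
    umi: str
    clone_id: int
    v_allele: str
    d_allele: str
    j_allele: str
    shm_positions: tuple[int, ...]
    cdr3_aa: str
    isotype: str


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random codons avoiding stop codons."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


def make_germline_set(config: SimulationConfig, rng: np.random.Generator | None = None) -> GermlineSet:
    """Random but structurally valid heavy-chain germline set.

    V genes: 96 random in-frame codons, the conserved Cys codon, and two
    codons reaching into CDR3 (anchor offset 288).  J genes: two CDR3-tail
    codons, the conserved Trp codon (anchor offset 6) and the FR4 peptide
    ending in the species anchor motif.  D genes: 15 random nucleotides.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes: list[GermlineGene] = []
    for i in range(config.n_v):
        seq = _random_codons(rng, 96) + "TGT" + encode_aa("AR")
        genes.append(
            GermlineGene(
                allele_name=f"IGHV{i + 1}-1*01",
                gene_class="V",
                chain="IGH",
                sequence=seq,
                subgroup=f"IGHV{i + 1}",
                cdr3_anchor=288,
            )
        )
    for i in range(config.n_d):
        seq = "".join(rng.choice(list(_BASES), size=15))
        genes.append(
            GermlineGene(
                allele_name=f"IGHD{i + 1}-1*01",
                gene_class="D",
                chain="IGH",
                sequence=seq,
                subgroup=f"IGHD{i + 1}",
            )
        )
    j_tail = encode_aa(J_CDR3_TAIL_AA)
    fr4 = encode_aa(FR4_TAIL[config.species])
    for i in range(config.n_j):
        # J genes share the FR4 motif but differ in their CDR3-proximal codons
        seq = _random_codons(rng, 1) + j_tail[3:] + "TGG" + fr4
        genes.append(
            GermlineGene(
                allele_name=f"IGHJ{i + 1}*01",
                gene_class="J",
                chain="IGH",
                sequence=seq,
                subgroup=f"IGHJ{i + 1}",
                cdr3_anchor=6,
            )
        )
    return GermlineSet(species=config.species, genes=genes)


def _constant_stub(isotype: str, species: str) -> str:
    """Constant-region stub nt beginning with the isotype fingerprint peptide."""
    table = BUILTIN_TABLES[species]
    key = isotype[2:] if isotype.startswith("Ig") else isotype
    peptide = table.fingerprints[key][0]
    # generic padding so even the short fingerprints leave room for matching
    return encode_aa(peptide + "GGSGGSGG")


def _translate_ok(nt: str) -> bool:
    return all(nt[i : i + 3] not in STOP_CODONS for i in range(0, len(nt) - 2, 3))


@dataclass
class _Clone:
    clone_id: int
    v: GermlineGene
    d: GermlineGene | None
    j: GermlineGene
    junction: str
    isotype: str
    amplicon: str
    cdr3_aa: str


def _build_clone(
    clone_id: int,
    germlines: GermlineSet,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> _Clone:
    from Bio.Seq import Seq

    v_genes = germlines.select("IGH", "V")
    d_genes = germlines.select("IGH", "D")
    j_genes = germlines.select("IGH", "J")
    v = v_genes[int(rng.integers(len(v_genes)))]
    j = j_genes[int(rng.integers(len(j_genes)))]
    d = d_genes[int(rng.integers(len(d_genes)))] if d_genes else None
    labels = list(config.isotype_mix)
    isotype = labels[int(rng.choice(len(labels), p=[config.isotype_mix[k] for k in labels]))]
    stub = _constant_stub(isotype, config.species)

    for _ in range(200):
        n1 = "".join(rng.choice(list(_BASES), size=int(rng.integers(0, 7))))
        n2 = "".join(rng.choice(list(_BASES), size=int(rng.integers(0, 7))))
        junction = n1 + (d.sequence if d is not None else "") + n2
        pad = (-len(junction)) % 3
        junction += "".join(rng.choice(list(_BASES), size=pad))
        amplicon = v.sequence + junction + j.sequence + stub
        if _translate_ok(amplicon):
            break
    else:
        raise RuntimeError("could not build a stop-free junction in 200 attempts")

    cdr3_nt = amplicon[v.cdr3_anchor : len(v.sequence) + len(junction) + j.cdr3_anchor + 3]
    cdr3_aa = str(Seq(cdr3_nt).translate())
    return _Clone(
        clone_id=clone_id,
        v=v,
        d=d,
        j=j,
        junction=junction,
        isotype=isotype,
        amplicon=amplicon,
        cdr3_aa=cdr3_aa,
    )


def _apply_shm(
    amplicon: str, v_len: int, n_mut: int, rng: np.random.Generator
) -> tuple[str, tuple[int, ...]]:
    """Inject substitutions into the V span, resampling any that create a stop."""
    seq = list(amplicon)
    positions: list[int] = []
    attempts = 0
    while len(positions) < n_mut and attempts < 50 * max(n_mut, 1):
        attempts += 1
        pos = int(rng.integers(v_len))
        if pos in positions:
            continue
        old = seq[pos]
        new = _BASES[int(rng.integers(4))]
        if new == old:
            continue
        seq[pos] = new
        codon_start = 3 * (pos // 3)
        if "".join(seq[codon_start : codon_start + 3]) in STOP_CODONS:
            seq[pos] = old
            continue
        positions.append(pos)
    return "".join(seq), tuple(sorted(positions))


def _clone_weights(n: int, exponent: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** (-exponent)
    return w / w.sum()


def simulate_repertoire(
    germlines: GermlineSet, config: SimulationConfig
) -> tuple[list[list[SimulatedRead]], pd.DataFrame]:
    """Simulate per-replicate reads with complete ground truth.

    Returns one read list per replicate plus a tidy ground-truth table (one
    row per emitted read).  A fraction ``replicate_overlap_frac`` of the
    clones is present in every replicate; the remainder are distributed
    round-robin across replicates, so replicates share most expanded clones
    but also carry private ones.
    """
    rng = np.random.default_rng(config.seed)
    clones = [_build_clone(i, germlines, config, rng) for i in range(config.n_clones)]

    n_shared = int(round(config.replicate_overlap_frac * config.n_clones))
    membership: list[list[int]] = [[] for _ in range(config.n_replicates)]
    for idx in range(config.n_clones):
        if idx < n_shared or config.n_replicates == 1:
            for rep in membership:
                rep.append(idx)
        else:
            membership[idx % config.n_replicates].append(idx)

    replicates: list[list[SimulatedRead]] = []
    for rep_i in range(config.n_replicates):
        clone_ids = membership[rep_i]
        if config.clone_sizes is not None:
            sizes = {
                cid: config.clone_sizes[cid] for cid in clone_ids if cid < len(config.clone_sizes)
            }
        else:
            weights = _clone_weights(len(clone_ids), config.clone_size_exponent)
            draw = rng.multinomial(config.n_reads, weights)
            sizes = {cid: int(c) for cid, c in zip(clone_ids, draw)}
        reads: list[SimulatedRead] = []
        read_index = 0
        for cid in clone_ids:
            clone = clones[cid]
            for _ in range(sizes.get(cid, 0)):
                n_mut = int(rng.poisson(config.shm_rate)) if config.shm_rate > 0 else 0
                seq, positions = _apply_shm(clone.amplicon, len(clone.v.sequence), n_mut, rng)
                umi = (
                    "".join(rng.choice(list(_BASES), size=config.umi_length))
                    if config.umi_length
                    else ""
                )
                for _copy in range(config.reads_per_molecule):
                    reads.append(
                        SimulatedRead(
                            replicate=rep_i,
                            read_index=read_index,
                            amplicon=seq,
                            umi=umi,
                            clone_id=cid,
                            v_allele=clone.v.allele_name,
                            d_allele=clone.d.allele_name if clone.d else "none",
                            j_allele=clone.j.allele_name,
                            shm_positions=positions,
                            cdr3_aa=clone.cdr3_aa,
                            isotype=clone.isotype,
                        )
                    )
                    read_index += 1
        replicates.append(reads)

    truth = pd.DataFrame(
        [
            {
                "replicate": r.replicate,
                "read_index": r.read_index,
                "clone_id": r.clone_id,
                "v_allele": r.v_allele,
                "d_allele": r.d_allele,
                "j_allele": r.j_allele,
                "n_shm": len(r.shm_positions),
                "shm_positions": ",".join(map(str, r.shm_positions)),
                "cdr3_aa": r.cdr3_aa,
                "isotype": r.isotype,
                "umi": r.umi,
                "amplicon": r.amplicon,
            }
            for rep in replicates
            for r in rep
        ]
    )
    return replicates, truth


def emit_fastq_pairs(
    reads: list[SimulatedRead],
    config: SimulationConfig,
    r1_path: str | Path,
    r2_path: str | Path,
    rng: np.random.Generator | None = None,
) -> None:
    """Write one replicate's reads as paired FASTQ (Phred+33).

    Forward read = 5' UMI + amplicon prefix; reverse read = reverse
    complement of the amplicon suffix.  Overlap of the mates is guaranteed
    whenever ``2 * read_length > len(amplicon) + umi_length``.  Sequencing
    errors are injected per base at ``seq_error_rate``; error positions get
    quality Q12, everything else Q35.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 7)
    q_hi = chr(35 + 33)
    q_lo = chr(12 + 33)

    def corrupt(seq: str) -> tuple[str, str]:
        if config.seq_error_rate <= 0:
            return seq, q_hi * len(seq)
        arr = list(seq)
        qual = [q_hi] * len(seq)
        hits = np.nonzero(rng.random(len(seq)) < config.seq_error_rate)[0]
        for pos in hits:
            alternatives = [b for b in _BASES if b != arr[pos]]
            arr[pos] = alternatives[int(rng.integers(3))]
            qual[pos] = q_lo
        return "".join(arr), "".join(qual)

    with open(r1_path, "w") as r1, open(r2_path, "w") as r2:
        for r in reads:
            fwd_payload = r.amplicon[: config.read_length - len(r.umi)]
            fwd = r.umi + fwd_payload
            rev = reverse_complement(r.amplicon[-config.read_length :])
            fseq, fqual = corrupt(fwd)
            # the UMI itself is kept error-free so group identity is exact
            if r.umi:
                fseq = r.umi + fseq[len(r.umi) :]
                fqual = q_hi * len(r.umi) + fqual[len(r.umi) :]
            rseq, rqual = corrupt(rev)
            name = f"sim:{r.replicate}:{r.read_index}"
            r1.write(f"@{name}/1\n{fseq}\n+\n{fqual}\n")
            r2.write(f"@{name}/2\n{rseq}\n+\n{rqual}\n")


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate a complete dataset on disk: germline FASTA, per-replicate
    paired FASTQ and the ground-truth TSV.  Returns the path manifest and the
    in-memory objects for direct use in tests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    germlines = make_germline_set(config, rng)
    germline_path = outdir / "germline.fasta"
    write_germline_set(germlines, germline_path)
    replicates, truth = simulate_repertoire(germlines, config)
    fastq_paths = []
    for i, reads in enumerate(replicates):
        r1 = outdir / f"replicate{i + 1}_R1.fastq"
        r2 = outdir / f"replicate{i + 1}_R2.fastq"
        emit_fastq_pairs(reads, config, r1, r2, np.random.default_rng(config.seed + 1000 + i))
        fastq_paths.append((r1, r2))
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return {
        "germline": germline_path,
        "fastq": fastq_paths,
        "truth": truth_path,
        "germline_set": germlines,
        "reads": replicates,
        "truth_df": truth,
    }
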