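# Methods

This note documents the models, procedures and numerical choices behind
`igkit`, and what the synthetic-data tests do and do not demonstrate about
real data.

## Germline references

Germline V/D/J sets are plain FASTA with pipe-delimited header metadata
(`allele_name|gene_class|chain|subgroup[|cdr3_anchor]`). The CDR3 anchor —
the 0-based offset of the conserved Cys codon (V) or FR4-anchor Trp/Phe
codon (J) — is mandatory for V and J genes so that CDR3 delineation is pure
coordinate mapping and never motif-guessing inside germline sequences. All
coordinates are 0-based, half-open. Subgroups are parsed as the text before
the first `-`, falling back to the text before the first `*`, else the full
name; this matches the common family-level naming convention
(`IGHV1-69*01 → IGHV1`, `IGHJ4*02 → IGHJ4`). Novel alleles may be appended
from a second FASTA; name collisions replace the base entry and are logged.
Partial alleles are accepted at any length ≥ 30 nt — a deliberate choice, as
provisional alleles are often incomplete.

## Preprocessing

**Merging.** The reverse mate is reverse-complemented and slid along the
forward mate; each offset with ≥ 20 nt overlap is scored as matches −
mismatches and offsets with > 10% mismatches are discarded. At disagreeing
positions the higher-Phred base wins (ties → forward mate) and the retained
quality is the per-position maximum. No acceptable offset ⇒ the pair is
rejected as non-overlapping. The 20 nt / 10% defaults are conventional
values for overlap mergers of 2 × 250 bp amplicon data.

**UMIs.** The IUPAC pattern is matched against the 5′ prefix of the
targeted mate(s); fixed positions must match exactly, degenerate positions
are captured. With UMIs on both mates the captures concatenate
forward-then-reverse. Groups are formed by exact UMI equality; within a
group, reads of the modal length take a per-position majority vote (ties:
highest summed Phred, then alphabetical; consensus quality = max Phred
among agreeing bases), while off-length reads stay as their own singletons —
no alignment rule exists for unequal-length duplicates and they are rare.
Consensus `count` fields record group sizes, so read counts are conserved.

**Filtering.** Four criteria: stop codon in the variable-region ORF, no
mate overlap, merged length < 300 nt, read quality < 20. "Read quality" is
interpreted as the *mean* Phred of the merged read (a minimum-per-base
alternative is configurable) — the aggregate is otherwise unspecified in
common usage. Overlap failures are consumed at merge time and forwarded
into the report; a record failing several of the remaining criteria is
counted once, in the order stop-codon → short → low-quality, so
`input = retained + Σ rejections` holds exactly. UMI collapsing runs after
merging and before filtering, so consensus-corrected molecules are what get
filtered.

## Annotation

The annotator is deliberately minimal: a fit alignment (whole germline
anywhere inside the read; free end gaps on the read) under match +2 /
mismatch −2 / gap open −6 / gap extend −1 picks the best V, then the best J
on the suffix right of the V span; ties break by score, then fewer
mutations, then lexicographic allele name. Reads whose best V score falls
below 50 (25 matched bases' worth of score) are excluded as unannotatable.
A pre-annotated AIRR-style rearrangement TSV can be ingested instead, so
any external annotator can replace the built-in one.

The reading frame is the V gene's frame mapped onto the read. The CDR3
spans from the read image of the V Cys anchor through the read image of the
J anchor codon *inclusive* (both anchor residues belong to the CDR3; reads
where a junction indel knocks the anchors out of frame are excluded as
CDR3-undefined). D segments are called by the longest exact substring match
of the V–J junction against the D set, requiring ≥ 5 nt — below that,
coincidental matches dominate.

Records group reads by `(chain, isotype, amino-acid sequence)`: grouping
across isotypes would erase the isotype report column. Counts sum; the
representative nucleotide sequence is the most frequent variant; subgroup
conflicts resolve by read-count plurality. Chain labels map IGH→VH, IGK→Vκ,
IGL→Vλ.

## Isotypes

The FR4 anchor (`VTVSS` human; `VTVSS`/`LTVSS`/`VTVSA` mouse) is located at
its *rightmost* occurrence — germline FR1–FR3 cannot contain it, but
hypermutation could create a spurious earlier copy. The sub-sequence after
the anchor is compared to the per-isotype fingerprint peptides; an exact
prefix match assigns directly, otherwise the isotype at unique minimum
Hamming distance ≤ 1 wins, and ties or distances > 1 give "unknown". The
murine IgG fingerprint `AKTT[A/P]P` is expanded to the two literals
`AKTTAP`/`AKTTPP`. The human IgA subclasses share the short `ASPTSP`
fingerprint and are discriminated by their long fingerprints (ending
`CSTQP` for A1, `DSTPQ` for A2, as tabulated); when the read is too short
to reach the tail the label falls back to `IgA`. Isotypes apply to heavy
chains only; light-chain records carry "none". Tables are YAML-editable to
extend species coverage.

## Repertoire statistics

All distributions count one vote per unique amino-acid sequence — this is
the defined unit for subgroup usage, and CDR3-length, SHM and isotype
tables use the same unit for internal consistency. SHM is counted over the
V-gene span only (mismatched aligned positions plus one per indel event);
J-gene mutations are not part of the headline statistics. Ka/Ks compares
each fully aligned, frame-consistent codon to its germline codon — codons
disrupted by indels are excluded — and classifies a changed codon once
(non-synonymous if the translations differ), normalizing by codons
compared; hence Ka + Ks ≤ 1 per codon and multi-nucleotide changes within
one codon count once. Undefined ratios (Ks = 0) are omitted from the ratio
data rather than set to a sentinel.

## Clones

A clone is all records with an identical CDR3 amino-acid sequence,
including the anchor residues as delineated above. Light chains cluster per
chain by the same rule when enabled. Ranking is by *y* (reads) descending,
ties by *x* then CDR3 string; the report keeps the top *K* = 100 by
default. Per-clone alignments use the center-star method (center = member
with the highest read count; pairwise global alignments under BLOSUM62,
gap open −10 / extend −1, merged once-a-gap-always-a-gap) — adequate for
the highly similar sequences inside a clone and dependency-free; it is not
a general-purpose MSA. Consensus is the per-column plurality (residue ties
alphabetical; columns with a gap majority dropped); the representative is
the member with the highest identity fraction against the consensus in a
global alignment. Logo matrices weight rows by read counts (an unweighted
mode exists).

## Joint analysis

Replicates aggregate by the record grouping key into per-replicate count
vectors (1–6 replicates; more are refused). Pearson correlation defaults to
the union of records with zero-fill — low-abundance scatter is part of the
reproducibility signal — with an intersection mode and a within-replicate
frequency mode available; undefined correlations (zero variance, < 2
points) are reported as missing, never as 0. Venn region counts partition
the union exactly (each sequence counted under the exact subset of
replicates containing it); a diagram is rendered for ≤ 3 replicates, the
table always. Joint statistics and clones re-run on the aggregated records
with total counts.

## MS database

Heavy-chain sequences are truncated at the FR4 anchor end and a cleavage
suffix is appended (`ASTK` human, `AK` mouse, per-isotype overrides
supported): the suffix replaces the constant-region fingerprint residues
rather than extending them, since the cleavage site must sit at the
variable-region C terminus; `keep_constant_tail=True` appends without
truncating for users who want the untrimmed sequence. The AA→DNA map lists,
under each amino-acid sequence, every supporting nucleotide variant with
the 0-based indices of its originating FASTQ reads; the indices partition
the retained reads.

## The simulator

The generator emulates overlapping 2 × 250 bp paired-end amplicon
sequencing of a heavy-chain repertoire. Germline V genes are 96 random
in-frame stop-free codons plus the conserved Cys codon and two codons
reaching into CDR3; J genes carry two CDR3-tail codons, the conserved Trp
codon and an FR4 peptide ending in the species anchor motif (each J gets a
distinct leading codon so alleles remain distinguishable); D segments are
15 random nucleotides. Clones recombine V + junction(+D) + J + a
constant-region stub beginning with the isotype fingerprint; junction
lengths are multiples of 3 and junctions are resampled until stop-free.
SHM is Poisson-distributed substitutions per read within the V gene
(default mean 4, a mid-range load for class-switched repertoires),
resampled to avoid stop codons. Sequencing errors are i.i.d. per base
(default 0.2%, a typical post-filter short-read rate) with a two-tier
quality model: Q35 baseline, Q12 at error sites — enough to exercise the
quality filter, not a calibrated error profile. The UMI itself is written
error-free so group identity stays exact; real UMIs accumulate errors and
require network-based grouping, which is out of scope. The default isotype
mix (IgM 0.3 / IgG 0.5 / IgA1 0.15 / IgE 0.05) is a serum-like blend.
Replicates share a configurable fraction of clones (default 0.5); the rest
distribute round-robin. All randomness flows through one seeded generator;
outputs are byte-reproducible.

Passing tests on this generator demonstrate algorithmic correctness —
exact recovery under zero noise, majority-vote behaviour under controlled
noise, count conservation — not performance on real data, which adds
primer bias, chimeras, position-dependent error profiles, indel errors and
germline alleles absent from the reference.

## Problem sizes and determinism

The test-suite round trip uses 3 replicates × 2,000 reads (error-free),
sizes at which recovery is provably exact and the whole suite stays fast;
statistical checks (SHM mean, UMI consensus recovery) use seeded
generators with tolerance bands of ≥ 3 standard errors. The acceptance
script re-simulates at the same sizes from a user-supplied seed. All
TSV/FASTA outputs are byte-identical across reruns with the same inputs;
plots are optional and excluded from that guarantee.

## Known limitations

No paired-end partial-alignment rescue or adapter chemistry beyond UMI
prefixes; subgroup-level (not allele-level) reporting in the statistics;
identity-only clone definition (similarity-threshold clustering is a
non-goal); no lineage trees, no SHM hotspot models, no statistical tests
between repertoires; no in-silico digestion or spectral search for the MS
database.
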