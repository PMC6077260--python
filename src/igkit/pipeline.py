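"""End-to-end orchestration: individual replicate runs and the joint run.

``run_individual`` executes merge -> UMI -> annotate -> filter -> isotype ->
statistics -> clones -> exports for one replicate and writes every artifact
(plus a checksum manifest) into its own directory; ``run_joint`` runs all
replicates, aggregates them and adds correlations, Venn intersections, joint
statistics/clones and the joint FASTA.  All result files are plain TSV/FASTA
so reruns are diffable; reruns with identical inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clonal, stats
from .annotate import (
    AnnotatedRead,
    AnnotationRecord,
    Annotator,
    build_annotation_records,
    ingest_airr,
)
from .errors import InputError
from .germline import GermlineSet, load_germline_set, merge_novel_alleles
from .io import (
    read_fastq_pairs,
    write_annotation_tsv,
    write_chain_fasta,
    write_manifest,
    write_tsv,
)
from .isotype import BUILTIN_TABLES, IsotypeTable, assign_isotype
from .joint import (
    JointRepertoire,
    MAX_REPLICATES,
    aggregate_replicates,
    correlation_matrix,
    joint_fasta,
    venn_counts,
)
from .msdb import CleavageRule, aa_to_dna_map, append_cleavage_suffix, write_ms_fasta
from .preprocess import (
    FilterConfig,
    MergedRead,
    apply_filters,
    collapse_umi_groups,
    extract_umi,
    merge_pair,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``replicates`` holds 1-6 entries, each either a ``(R1, R2)`` FASTQ pair
    or a single AIRR-style rearrangement TSV path (the two entry points can
    not be mixed within a run).
    """

    replicates: list
    germline: str | Path | None = None
    extra_germline: str | Path | None = None
    species: str = "human"
    chains: list[str] | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    umi_pattern: str | None = None
    umi_location: str = "forward"
    min_overlap: int = 20
    max_mismatch_frac: float = 0.1
    k_top_clones: int = clonal.DEFAULT_TOP_K
    ms_suffix: str | None = None
    ms_suffix_isotype: dict[str, str] = field(default_factory=dict)
    keep_constant_tail: bool = False
    outdir: str | Path = "igkit_results"
    plots: bool = False
    airr_input: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.replicates) <= MAX_REPLICATES:
            raise InputError(
                f"replicate count must be within 1..{MAX_REPLICATES}, "
                f"got {len(self.replicates)}"
            )
        if not self.airr_input and self.germline is None:
            raise InputError("a germline FASTA is required for FASTQ input")


def load_references(config: RunConfig) -> GermlineSet | None:
    if config.airr_input:
        return None
    gset = load_germline_set(config.germline, config.species)
    if config.extra_germline:
        gset = merge_novel_alleles(
            gset, load_germline_set(config.extra_germline, config.species)
        )
    return gset


@dataclass
class IndividualResult:
    records: list[AnnotationRecord]
    clones: list[clonal.Clone]
    filter_report: object | None
    outdir: Path
    annotation_failures: dict[str, int] = field(default_factory=dict)


def _preprocess_replicate(
    r1: str | Path, r2: str | Path, config: RunConfig
) -> tuple[list[MergedRead], int, int]:
    """FASTQ pair -> merged (and UMI-collapsed) reads.

    Returns (merged reads, no-overlap count, umi-unmatched count).
    """
    no_overlap = 0
    umi_unmatched = 0
    merged: list[MergedRead] = []
    for pair in read_fastq_pairs(r1, r2):
        umi = None
        if config.umi_pattern:
            hit = extract_umi(pair, config.umi_pattern, config.umi_location)
            if hit is None:
                umi_unmatched += 1
                continue
            umi, pair = hit
        m = merge_pair(pair, config.min_overlap, config.max_mismatch_frac)
        if m is None:
            no_overlap += 1
            continue
        m.umi = umi
        merged.append(m)
    if config.umi_pattern:
        merged = collapse_umi_groups(merged)
    return merged, no_overlap, umi_unmatched


def _annotate_reads(
    merged: list[MergedRead], annotator: Annotator, table: IsotypeTable
) -> list[AnnotatedRead]:
    """Annotate merged reads, caching by sequence (duplicates are common)."""
    cache: dict[str, AnnotatedRead | None] = {}
    annotated: list[AnnotatedRead] = []
    for read in merged:
        if read.sequence in cache:
            template = cache[read.sequence]
        else:
            template = annotator.annotate(read)
            if template is not None:
                if template.chain == "IGH":
                    template.isotype = assign_isotype(template.full_aa, table)
                else:
                    template.isotype = "none"
            cache[read.sequence] = template
        if template is None:
            continue
        annotated.append(dataclasses.replace(template, merged=read))
    return annotated


def _emit_statistics(
    records: list[AnnotationRecord],
    germlines: GermlineSet | None,
    outdir: Path,
    config: RunConfig,
    prefix: str = "",
) -> list[Path]:
    paths = []

    def emit(name: str, df: pd.DataFrame) -> None:
        p = outdir / f"{prefix}{name}.tsv"
        write_tsv(df, p)
        paths.append(p)

    emit("cdr3_length_distribution", stats.cdr3_length_distribution(records))
    emit("v_subgroup_usage", stats.subgroup_usage(records, "V"))
    emit("d_subgroup_usage", stats.subgroup_usage(records, "D"))
    emit("j_subgroup_usage", stats.subgroup_usage(records, "J"))
    emit("vj_combination_usage", stats.vdj_combination_usage(records, include_d=False))
    emit("vdj_combination_usage", stats.vdj_combination_usage(records, include_d=True))
    emit("isotype_distribution", stats.isotype_distribution(records))
    if germlines is not None:
        emit("shm_histogram", stats.shm_histogram(records))
        profiles = stats.mutation_profiles(records, germlines)
        emit("mutation_profiles", profiles)
    if config.plots:
        from . import plots

        plots.bar_chart(
            stats.cdr3_length_distribution(records),
            outdir / f"{prefix}cdr3_length_distribution.png",
            "CDR3 length distribution",
            "CDR3 length (AA)",
        )
        plots.bar_chart(
            stats.subgroup_usage(records, "V"),
            outdir / f"{prefix}v_subgroup_usage.png",
            "V subgroup usage",
            "subgroup",
        )
        plots.pie_chart(
            stats.isotype_distribution(records),
            outdir / f"{prefix}isotype_distribution.png",
            "isotype distribution",
        )
        if germlines is not None:
            plots.bar_chart(
                stats.shm_histogram(records),
                outdir / f"{prefix}shm_histogram.png",
                "somatic hypermutation",
                "mutations per read",
            )
            plots.kaks_boxplot(
                stats.mutation_profiles(records, germlines),
                outdir / f"{prefix}kaks_boxplot.png",
            )
    return paths


def _emit_clonal(
    records: list[AnnotationRecord], outdir: Path, config: RunConfig, prefix: str = ""
) -> tuple[list[clonal.Clone], list[Path]]:
    paths = []
    heavy = [r for r in records if r.chain == "VH"]
    clones = clonal.cluster_clones(heavy)
    top = [clonal.analyze_clone(c) for c in clonal.top_k_clones(clones, config.k_top_clones)]
    p = outdir / f"{prefix}clones.tsv"
    write_tsv(clonal.clone_table(top), p)
    paths.append(p)
    p = outdir / f"{prefix}clonal_expansion.tsv"
    write_tsv(clonal.expansion_table(clones), p)
    paths.append(p)

    msa_dir = outdir / f"{prefix}clone_alignments"
    msa_dir.mkdir(exist_ok=True)
    for rank, clone in enumerate(top, start=1):
        msa = clonal.align_clone_members(clone)
        fasta = msa_dir / f"clone_{rank:03d}.fasta"
        with open(fasta, "w") as fh:
            for j, ((_aa, count, _nt), row) in enumerate(zip(clone.members, msa), start=1):
                fh.write(f">member_{j}|counts={count}\n{row}\n")
        paths.append(fasta)
        logo = clonal.sequence_logo_matrix(msa, [c for _, c, _ in clone.members])
        logo_path = msa_dir / f"clone_{rank:03d}_logo.tsv"
        write_tsv(logo, logo_path)
        paths.append(logo_path)
    if config.plots:
        from . import plots

        plots.expansion_plot(
            clonal.expansion_table(clones),
            outdir / f"{prefix}clonal_expansion.png",
            config.k_top_clones,
        )
    return clones, paths


def _emit_exports(
    records: list[AnnotationRecord], outdir: Path, config: RunConfig, prefix: str = ""
) -> list[Path]:
    paths = []
    chain_files = {"VH": "V_H", "Vκ": "V_K", "Vλ": "V_L"}
    for chain, stem in chain_files.items():
        chain_records = [r for r in records if r.chain == chain]
        if not chain_records:
            continue
        fasta = outdir / f"{prefix}{stem}_AA_Sequences.fasta"
        write_chain_fasta(chain_records, fasta)
        paths.append(fasta)
        mapping = outdir / f"{prefix}{stem}_AA_TO_DNA_reads.fasta"
        aa_to_dna_map(chain_records, mapping)
        paths.append(mapping)
        if chain == "VH":
            rule = CleavageRule(
                species=config.species,
                default_suffix=config.ms_suffix,
                isotype_suffixes=config.ms_suffix_isotype,
            )
            suffixed = append_cleavage_suffix(
                chain_records,
                rule,
                BUILTIN_TABLES[config.species],
                keep_constant_tail=config.keep_constant_tail,
            )
            ms_path = outdir / f"{prefix}{stem}_AA_Sequences_MS.fasta"
            write_ms_fasta(suffixed, ms_path)
            paths.append(ms_path)
    return paths


def run_individual(
    config: RunConfig,
    replicate_index: int,
    germlines: GermlineSet | None = None,
) -> IndividualResult:
    """Analyze one replicate end to end; artifacts go to ``<outdir>/replicate_<i>``."""
    t0 = time.time()
    outdir = Path(config.outdir) / f"replicate_{replicate_index + 1}"
    outdir.mkdir(parents=True, exist_ok=True)
    entry = config.replicates[replicate_index]
    artifacts: list[Path] = []
    failures: dict[str, int] = {}

    if config.airr_input:
        logger.info("replicate %d: AIRR ingestion (merge/UMI stages skipped)", replicate_index + 1)
        records = ingest_airr(entry)
        report = None
    else:
        if germlines is None:
            germlines = load_references(config)
        r1, r2 = entry
        merged, no_overlap, umi_unmatched = _preprocess_replicate(r1, r2, config)
        annotator = Annotator(germlines, chains=config.chains)
        table = BUILTIN_TABLES[config.species]
        annotated = _annotate_reads(merged, annotator, table)
        failures = dict(annotator.failures)
        failures["umi_unmatched"] = umi_unmatched
        retained, report = apply_filters(annotated, config.filter_config, no_overlap)
        records = build_annotation_records(retained)
        p = outdir / "filter_report.tsv"
        write_tsv(pd.DataFrame(report.as_rows(), columns=["criterion", "count"]), p)
        artifacts.append(p)

    for chain in sorted({r.chain for r in records}):
        chain_records = [r for r in records if r.chain == chain]
        stem = {"VH": "IGH", "Vκ": "IGK", "Vλ": "IGL"}[chain]
        p = outdir / f"{stem}_aa_sequence_annotations.tsv"
        write_annotation_tsv(chain_records, p)
        artifacts.append(p)

    artifacts += _emit_statistics(records, germlines if not config.airr_input else None, outdir, config)
    clones, clone_paths = _emit_clonal(records, outdir, config)
    artifacts += clone_paths
    artifacts += _emit_exports(records, outdir, config)

    write_manifest(artifacts, outdir / "manifest.tsv")
    logger.info(
        "replicate %d: %d records, %d clones in %.1fs",
        replicate_index + 1,
        len(records),
        len(clones),
        time.time() - t0,
    )
    return IndividualResult(
        records=records,
        clones=clones,
        filter_report=report,
        outdir=outdir,
        annotation_failures=failures,
    )


def run_joint(config: RunConfig) -> tuple[list[IndividualResult], JointRepertoire | None]:
    """Run every replicate individually, then the joint aggregation.

    With a single replicate the joint outputs are skipped (with a notice);
    more than six replicates are refused by :class:`RunConfig`.
    """
    germlines = load_references(config)
    results = [
        run_individual(config, i, germlines) for i in range(len(config.replicates))
    ]
    if len(results) == 1:
        logger.info("single replicate: joint analysis skipped")
        return results, None

    joint = aggregate_replicates([r.records for r in results])
    outdir = Path(config.outdir) / "joint"
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    # joint annotation table: the 9 report columns plus per-replicate counts
    rows = []
    for rec, vec in zip(joint.records, joint.per_replicate_counts):
        row = dict(zip(AnnotationRecord.TSV_COLUMNS, rec.as_row()))
        for i, c in enumerate(vec):
            row[f"count_replicate_{i + 1}"] = c
        rows.append(row)
    p = outdir / "joint_aa_sequence_annotations.tsv"
    write_tsv(pd.DataFrame(rows), p)
    artifacts.append(p)

    mat = correlation_matrix(joint)
    p = outdir / "correlation_matrix.tsv"
    write_tsv(
        pd.DataFrame(
            mat,
            columns=[f"replicate_{i + 1}" for i in range(joint.n_replicates)],
        ),
        p,
    )
    artifacts.append(p)

    regions = venn_counts(joint)
    p = outdir / "venn.tsv"
    write_tsv(
        pd.DataFrame(
            [
                {
                    "replicates": "+".join(str(i + 1) for i in subset),
                    "unique_aa_sequences": n,
                }
                for subset, n in sorted(regions.items())
            ]
        ),
        p,
    )
    artifacts.append(p)
    if config.plots and joint.n_replicates <= 3:
        from . import plots

        plots.venn_diagram(regions, joint.n_replicates, outdir / "venn.png")

    p = outdir / "joint.fasta"
    joint_fasta(joint, p)
    artifacts.append(p)

    artifacts += _emit_statistics(joint.records, germlines, outdir, config, prefix="joint_")
    _, clone_paths = _emit_clonal(joint.records, outdir, config, prefix="joint_")
    artifacts += clone_paths
    artifacts += _emit_exports(joint.records, outdir, config, prefix="joint_")
    write_manifest(artifacts, outdir / "manifest.tsv")
    return results, joint
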