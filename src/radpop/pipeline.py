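"""End-to-end orchestration: simulate -> preprocess -> stacks -> catalog,
plus truth-based recovery scoring for benchmarking the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .catalog import (
    GenotypeMatrix,
    SelectionLog,
    match_loci_across_accessions,
    select_biallelic_snp_loci,
)
from .preprocess import PreprocessResult, preprocess_reads
from .simulate import SimulatedDataset, SimulationConfig, simulate_dataset
from .stacks import assemble_accession


@dataclass
class PipelineResult:
    dataset: SimulatedDataset
    preprocess: PreprocessResult
    matrix: GenotypeMatrix
    selection_log: SelectionLog
    paralog_conflicts: list = field(default_factory=list)


def run_pipeline(
    config: SimulationConfig,
    min_accessions: int = 14,
) -> PipelineResult:
    """Simulate a dataset and run the full SNP-discovery pipeline on it."""
    dataset = simulate_dataset(config)
    return run_on_dataset(dataset, min_accessions)


def run_on_dataset(
    dataset: SimulatedDataset, min_accessions: int = 14
) -> PipelineResult:
    config = dataset.config
    pre = preprocess_reads(dataset.reads, dataset.barcodes)
    loci_by_acc = {
        acc: assemble_accession(tags)[0]
        for acc, tags in pre.tags_by_accession.items()
    }
    entries, conflicts = match_loci_across_accessions(loci_by_acc)
    matrix, log = select_biallelic_snp_loci(
        entries,
        min_accessions=min_accessions,
        group_of=config.group_of,
        class_of_group=config.class_of_group,
        accessions=config.accessions,
    )
    return PipelineResult(
        dataset=dataset,
        preprocess=pre,
        matrix=matrix,
        selection_log=log,
        paralog_conflicts=conflicts,
    )


@dataclass
class RecoveryReport:
    """How faithfully the pipeline recovered the simulator's ground truth."""

    n_clean_truth: int
    n_recovered: int  # clean truth loci present in the catalog
    locus_recall: float
    n_genotypes_compared: int
    n_genotypes_correct: int
    genotype_concordance: float
    #: catalog locus id -> truth locus id for matched loci
    matched: dict[str, str] = field(default_factory=dict)

    # selected-set agreement (filled when a scan is scored)
    truth_selected: set = field(default_factory=set)
    called_selected: set = field(default_factory=set)
    precision: float | None = None
    recall: float | None = None


def _matrix_to_truth_map(matrix: GenotypeMatrix, truth) -> dict[str, str]:
    """Match catalog loci to truth loci by SNP-masked tag sequence."""
    def mask(tag: str, pos: int) -> str:
        return f"{tag[:pos]}.{tag[pos + 1:]}"

    truth_by_mask = {
        mask(row["tag"], int(row["pos"])): locus
        for locus, row in truth.loci.iterrows()
    }
    matched = {}
    for cat_id in matrix.loci:
        key = mask(matrix.consensus[cat_id], int(matrix.snp_pos[cat_id]))
        hit = truth_by_mask.get(key)
        if hit is not None:
            matched[cat_id] = hit
    return matched


def score_recovery(
    result: PipelineResult,
    scan: pd.DataFrame | None = None,
) -> RecoveryReport:
    """Score catalog completeness and genotype accuracy against the truth.

    Recovery is judged on *clean* truth loci: single-variant, non-repeat
    tags that are polymorphic and genotyped in enough accessions to be
    catalog-eligible. Genotype concordance compares non-missing calls at
    recovered loci with the true genotypes. When ``scan`` (a
    ``lod_selection_scan`` result) is given, the called selected set is
    scored as precision/recall against the truth's selected flags.
    """
    truth = result.dataset.truth
    matrix = result.matrix
    matched = _matrix_to_truth_map(matrix, truth)
    clean = set(truth.loci.index[truth.loci["clean"]])
    recovered = {c: t for c, t in matched.items() if t in clean}

    truth_codes = truth.genotype_codes()
    n_cmp = n_ok = 0
    for cat_id, t_id in recovered.items():
        # orient the catalog's ref/alt onto the truth allele pair
        t_ref, t_alt = truth.loci.at[t_id, "ref"], truth.loci.at[t_id, "alt"]
        c_ref, c_alt = matrix.ref[cat_id], matrix.alt[cat_id]
        if {c_ref, c_alt} != {t_ref, t_alt}:
            continue  # allele mismatch: count all its calls as wrong
        flip = c_ref != t_ref
        for acc in matrix.accessions:
            call = int(matrix.calls.at[cat_id, acc])
            tcode = int(truth_codes.at[t_id, acc])
            if call == -1 or tcode == -1:
                continue
            if flip:
                call = 2 - call
            n_cmp += 1
            n_ok += call == tcode
    report = RecoveryReport(
        n_clean_truth=len(clean),
        n_recovered=len(recovered),
        locus_recall=len(recovered) / len(clean) if clean else float("nan"),
        n_genotypes_compared=n_cmp,
        n_genotypes_correct=n_ok,
        genotype_concordance=n_ok / n_cmp if n_cmp else float("nan"),
        matched=matched,
    )
    if scan is not None:
        # score against selected loci the catalog could legitimately carry:
        # single-variant, non-repeat, sufficiently covered tags (two-variant
        # tags are excluded by the single-SNP filter, which is tested
        # separately)
        truth_sel = set(
            truth.loci.index[truth.loci["selected"] & truth.loci["clean"]]
        )
        called = {
            matched.get(cat_id)
            for cat_id in scan.index[scan["selected"]]
        } - {None}
        called &= clean  # same eligibility universe on both sides
        tp = len(called & truth_sel)
        report.truth_selected = truth_sel
        report.called_selected = called
        report.precision = tp / len(called) if called else float("nan")
        report.recall = tp / len(truth_sel) if truth_sel else float("nan")
    return report
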