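"""Per-sample and cohort pipeline orchestration.

The per-sample flow mirrors the self-reference calling strategy: place
reads competitively against the mtDNA and NUMT decoys, make initial calls,
build the per-sample consensus from homoplasmies, re-place and re-call
against the consensus in two passes (primary and shifted, with
control-region calls taken from the shifted pass), lift everything back to
reference coordinates, then apply variant QC and compute copy number.
Every stage emits one structured log record with input/output counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .caller import (
    AlignedRead,
    PlacementTarget,
    compute_mtcn,
    pileup_and_call,
    place_reads,
)
from .consensus import (
    build_consensus,
    lift_coverage,
    lift_sample_calls,
    select_consensus_edits,
)
from .qc import (
    CellState,
    HeteroplasmyMatrix,
    QCThresholds,
    SampleQCRecord,
    detect_homoplasmy_overlap,
    sample_qc,
    variant_qc,
)
from .reference import CircularGenome, RegionCatalog, build_shifted_genome
from .simulate import linearize_reads
from .variants import VariantCall

logger = logging.getLogger("mitokit.pipeline")

#: header line declaring conventions, written atop every output table
OUTPUT_HEADER = f"# mitokit v{__version__}; coordinates 1-based inclusive"


@dataclass
class PipelineConfig:
    homoplasmy_threshold: float = 0.95
    min_base_quality: int = 20
    min_alt_reads: int = 2
    shift: int | None = None  # default floor(L/2)
    kmer_size: int = 21
    nuc_mean_coverage: float = 30.0
    qc: QCThresholds = field(default_factory=QCThresholds)
    linear_mode: bool = True  # emulate linear alignment breakpoint loss


@dataclass
class SampleResult:
    sample_id: str
    calls: list[VariantCall]  # reference coordinates, post-liftover
    coverage: np.ndarray  # reference coordinates
    mtcn: float
    qc_record: SampleQCRecord
    cell_states: dict[str, CellState]
    consensus_edits: int


def _stage(name: str, n_in: int, n_out: int) -> None:
    logger.info("stage=%s n_in=%d n_out=%d", name, n_in, n_out)


def run_sample_pipeline(
    sample_id: str,
    reads: Sequence[AlignedRead],
    reference: CircularGenome,
    catalog: RegionCatalog,
    numt_targets: Sequence[PlacementTarget] = (),
    config: PipelineConfig | None = None,
    variants_of_interest: Sequence[str] | None = None,
) -> SampleResult:
    cfg = config or PipelineConfig()
    L = reference.length
    shift = cfg.shift if cfg.shift is not None else L // 2

    # 1. competitive placement against reference + decoys; placement decides
    #    the winning target, but the original alignment (position + CIGAR,
    #    which may carry indels) is kept for pileup
    targets = [PlacementTarget(reference.contig_name, reference)] + list(numt_targets)
    placed = place_reads(reads, targets, k=cfg.kmer_size)
    mt_ids = {
        r.read_id for r in placed if r.contig == reference.contig_name and r.usable
    }
    mt_reads = [r for r in reads if r.read_id in mt_ids and r.usable]
    _stage("place_reads", len(reads), len(mt_reads))

    # 2. initial calling to find homoplasmies
    _, calls0 = pileup_and_call(
        mt_reads, reference, cfg.min_base_quality, cfg.min_alt_reads
    )
    edits = select_consensus_edits(calls0, reference, cfg.homoplasmy_threshold)
    _stage("select_consensus_edits", len(calls0), len(edits))

    # 3. per-sample consensus
    consensus, cmap = build_consensus(reference, edits)
    shifted_consensus, smap = build_shifted_genome(consensus, shift)

    # 4. re-place against consensus + decoys, re-call in two passes; the
    #    winning reads keep their original CIGAR with the leftmost position
    #    mapped into consensus coordinates (exact for substitution edits)
    targets2 = [PlacementTarget(reference.contig_name, consensus)] + list(numt_targets)
    placed2 = place_reads(reads, targets2, k=cfg.kmer_size)
    mt2_ids = {
        r.read_id for r in placed2 if r.contig == reference.contig_name and r.usable
    }
    mt2 = [
        replace(r, left_pos=cmap.ref_to_cons(r.left_pos).pos)
        for r in reads
        if r.read_id in mt2_ids and r.usable
    ]
    _stage("replace_reads", len(reads), len(mt2))

    Lc = consensus.length
    if cfg.linear_mode:
        primary_reads = linearize_reads(mt2, Lc, 0)
        shifted_reads = linearize_reads(mt2, Lc, shift)
    else:
        primary_reads = list(mt2)
        shifted_reads = [
            replace(r, left_pos=smap.to_shifted(r.left_pos)) for r in mt2
        ]
    depth_p, calls_p = pileup_and_call(
        primary_reads, consensus, cfg.min_base_quality, cfg.min_alt_reads
    )
    depth_s, calls_s = pileup_and_call(
        shifted_reads, shifted_consensus, cfg.min_base_quality, cfg.min_alt_reads
    )

    # 5. dual-pass merge in consensus coordinates, CR membership evaluated
    #    on the lifted reference position
    def _in_cr(cons_pos: int) -> bool:
        ref_pos = cmap.cons_to_ref(((cons_pos - 1) % Lc) + 1).pos
        return catalog["control_region"].contains(ref_pos)

    merged = [c for c in calls_p if not _in_cr(c.pos)]
    for c in calls_s:
        cons_pos = smap.to_original(c.pos)
        if _in_cr(cons_pos):
            merged.append(replace(c, pos=cons_pos))
    merged.sort(key=lambda c: (c.pos, c.ref, c.alt))
    _stage("dual_pass_merge", len(calls_p) + len(calls_s), len(merged))

    # combined consensus-space coverage: shifted pass inside the CR
    cov_cons = depth_p.astype(float).copy()
    for cons_pos in range(1, Lc + 1):
        if _in_cr(cons_pos):
            cov_cons[cons_pos - 1] = depth_s[smap.to_shifted(cons_pos) - 1]

    # 6. liftover of calls and coverage
    lifted = lift_sample_calls(cmap, merged, reference, consensus)
    cov_ref = lift_coverage(cmap, cov_cons)
    # re-emitted edit calls carry no pileup depth of their own; back-fill
    # from the lifted coverage vector
    lifted = [
        replace(
            c,
            depth=int(cov_ref[c.pos - 1]),
            alt_depth=min(
                int(round(c.heteroplasmy * cov_ref[c.pos - 1])),
                int(cov_ref[c.pos - 1]),
            ),
        )
        if c.depth == 0
        else c
        for c in lifted
    ]
    _stage("liftover", len(merged), len(lifted))

    # 7. QC and copy number
    vids = (
        list(variants_of_interest)
        if variants_of_interest is not None
        else [c.variant_id for c in lifted]
    )
    states = variant_qc(lifted, cov_ref, vids, cfg.qc)
    mtcn = compute_mtcn(
        {"mean": float(cov_ref.mean()), "median": float(np.median(cov_ref))},
        cfg.nuc_mean_coverage,
    )
    qc_rec = SampleQCRecord(
        sample_id=sample_id,
        mtcn=mtcn,
        contamination=0.0,
        homoplasmy_overlap=detect_homoplasmy_overlap(lifted),
    )
    _stage("variant_qc", len(lifted), len(states))
    return SampleResult(
        sample_id=sample_id,
        calls=lifted,
        coverage=cov_ref,
        mtcn=mtcn,
        qc_record=qc_rec,
        cell_states=states,
        consensus_edits=len(edits),
    )


# ---------------------------------------------------------------------------
# Cohort pipeline
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    matrix: HeteroplasmyMatrix
    qc_records: list[SampleQCRecord]
    kept_samples: list[str]
    mtcn: pd.Series
    case_only: dict[str, pd.Series]
    case_control: dict[str, pd.Series]
    transmission: pd.DataFrame | None = None


def run_cohort_pipeline(
    sample_results: Sequence[SampleResult],
    pedigree: pd.DataFrame | None = None,
    excluded_years: set[int] = frozenset(),
    min_carriers: int = 2,
    config: PipelineConfig | None = None,
) -> CohortResult:
    """Aggregate per-sample results into cohort phenotypes.

    Builds the heteroplasmy matrix over the union of called variants,
    applies sample QC (QC-fail samples vanish from every downstream
    table), constructs case-only and case-control phenotypes for variants
    heteroplasmic in at least ``min_carriers`` kept samples, and emits
    transmission pairs when a pedigree is supplied.
    """
    from .phenotypes import build_case_control, build_case_only, transmission_pairs

    if len(sample_results) < 2:
        raise ValueError("cohort pipeline needs >= 2 samples")
    all_vids = sorted({v for r in sample_results for v in r.cell_states})
    cfg = config or PipelineConfig()
    cells = {}
    for r in sample_results:
        states = dict(r.cell_states)
        for vid in all_vids:
            if vid not in states:
                pos = int(vid.split(":")[1])
                depth_ok = r.coverage[pos - 1] >= cfg.qc.min_site_depth
                states[vid] = (
                    CellState("reference", 0.0) if depth_ok else CellState("missing")
                )
        cells[r.sample_id] = states
    matrix = HeteroplasmyMatrix.from_sample_states(cells)
    _stage("build_matrix", len(sample_results), len(all_vids))

    qc_records = sample_qc(
        [r.qc_record for r in sample_results], excluded_years=excluded_years
    )
    dropped = [r.sample_id for r in qc_records if not r.kept]
    matrix = matrix.drop_samples(dropped)
    kept = matrix.samples
    _stage("sample_qc", len(sample_results), len(kept))

    mtcn = pd.Series(
        {r.sample_id: r.mtcn for r in sample_results if r.sample_id in kept},
        name="mtCN",
    )
    case_only: dict[str, pd.Series] = {}
    case_control: dict[str, pd.Series] = {}
    for vid in matrix.variants:
        n_car = int((matrix.state[vid] == "heteroplasmic").sum())
        if n_car >= min_carriers:
            case_only[vid] = build_case_only(matrix, vid)
            case_control[vid] = build_case_control(matrix, vid)

    transmission = None
    if pedigree is not None and len(pedigree):
        transmission = transmission_pairs(matrix, pedigree, min_samples=min_carriers)
    return CohortResult(
        matrix=matrix,
        qc_records=qc_records,
        kept_samples=kept,
        mtcn=mtcn,
        case_only=case_only,
        case_control=case_control,
        transmission=transmission,
    )


def write_sample_outputs(result: SampleResult, out_dir: str | Path) -> None:
    from .caller import write_coverage_tsv
    from .variants import write_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contig = result.calls[0].contig if result.calls else "chrM"
    write_vcf(
        result.calls,
        out / f"{result.sample_id}.vcf",
        contig=contig,
        contig_length=len(result.coverage),
        sample=result.sample_id,
    )
    write_coverage_tsv(result.coverage, contig, out / f"{result.sample_id}.coverage.tsv")
    with open(out / f"{result.sample_id}.mtcn.tsv", "w") as fh:
        fh.write(OUTPUT_HEADER + "\n")
        fh.write("sample_id\tmtCN\tconsensus_edits\n")
        fh.write(f"{result.sample_id}\t{result.mtcn:.4f}\t{result.consensus_edits}\n")
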