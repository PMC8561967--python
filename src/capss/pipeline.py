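"""End-to-end orchestration: simulate -> demultiplex/filter -> short and
long BES extraction -> CAPSS deconvolution -> genome anchoring -> gap
accounting, with one structured log line and one set of plain-text
artifacts per stage.

The pipeline is deterministic for a fixed configuration: stage seeds are
derived from the single run seed, so rerunning a config reproduces every
artifact byte for byte.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .assign import (
    Policy,
    Source,
    assignment_stats,
    match_pools,
    merge_assignments,
    resolve_conflicts,
)
from .bes_long import LongBes, assemble_pool, extract_long_bes, n50
from .bes_short import End, ShortBes, cluster_and_consensus, find_junction_reads, trim_to_bes
from .config import RunConfig
from .gapstats import (
    CoverageReport,
    GapInterval,
    InsertStats,
    chromosome_coverage,
    covered_gaps,
    effective_clone_size_kb,
    find_gaps,
    insert_stats,
)
from .genmap import (
    GenomeIndex,
    HitClassification,
    MappedClone,
    OrganelleCall,
    align_bes,
    cull_and_classify,
    integrate,
    mask_repeats,
    pair_and_place,
    screen_organelle,
    write_gff3,
)
from .pool_design import Axis, PoolRef, SuperpoolLayout, build_index_table
from .preprocess import PoolReadSet, build_host_index, demultiplex, filter_host, quality_trim
from .seq import random_dna
from .simulate import (
    PooledReadSets,
    SyntheticGenome,
    TruthTables,
    VectorModel,
    build_truth_tables,
    default_vector,
    place_clones,
    simulate_genome,
    simulate_pool_reads,
)

logger = logging.getLogger("capss")

ORGANELLE_NAME = "chloroplast"


@dataclass
class SimulationBundle:
    """Everything the simulator stage produces, truth included."""

    genome: SyntheticGenome
    organelle: dict[str, str]
    host_genome: str
    vector: VectorModel
    index_table: dict[PoolRef, str]
    truth: TruthTables
    reads: PooledReadSets

    @property
    def all_sequences(self) -> dict[str, str]:
        return {**self.genome.sequences, **self.organelle}


@dataclass
class PipelineResult:
    config: RunConfig
    layout: SuperpoolLayout
    sim: SimulationBundle
    pools: dict[PoolRef, PoolReadSet]
    n_unassigned: int
    accounting: pd.DataFrame
    short_bes: list[ShortBes]
    long_bes: list[LongBes]
    pool_n50: pd.DataFrame
    assignments: dict[Source, dict] = field(default_factory=dict)
    n_filtered: dict[Source, int] = field(default_factory=dict)
    placed: dict[Source, dict] = field(default_factory=dict)
    discards: Counter = field(default_factory=Counter)
    final_clones: list[MappedClone] = field(default_factory=list)
    organelle_calls: list[OrganelleCall] = field(default_factory=list)
    gaps: list[GapInterval] = field(default_factory=list)
    covered: list[GapInterval] = field(default_factory=list)
    coverage: CoverageReport | None = None
    inserts: InsertStats | None = None
    summary: dict = field(default_factory=dict)


def stage_simulate(config: RunConfig) -> SimulationBundle:
    """Generate genome, organelle, host, vector, clone array and pooled reads."""
    sim = config.simulate
    layout = config.layout.build()
    genome = simulate_genome(
        n_chrom=sim.n_chrom,
        chrom_length=sim.chrom_length,
        n_gaps=sim.n_gaps,
        gap_length=sim.gap_length,
        repeat_unit_length=sim.repeat_unit_length,
        repeat_copies=sim.repeat_copies,
        gc=sim.gc,
        seed=config.seed,
        site_spacing=sim.site_spacing,
    )
    organelle_seq = simulate_genome(
        n_chrom=1,
        chrom_length=sim.organelle_length,
        n_gaps=0,
        gap_length=0,
        gc=sim.gc,
        seed=config.seed + 1,
        site_spacing=sim.site_spacing,
    ).sequences["chr01"]
    organelle = {ORGANELLE_NAME: organelle_seq}
    host_genome = random_dna(np.random.default_rng(config.seed + 2), sim.host_length, gc=0.5)
    vector = default_vector(flank_len=sim.flank_len, seed=config.seed + 3)
    index_table = build_index_table(layout)
    clones = place_clones(
        genome,
        layout,
        insert_mean=sim.insert_mean,
        insert_sd=sim.insert_sd,
        insert_min=sim.insert_min,
        insert_max=sim.insert_max,
        organelle_fraction=sim.organelle_fraction,
        organelle_genome=organelle if sim.organelle_fraction > 0 else None,
        seed=config.seed + 4,
        unique_ends=sim.unique_ends,
    )
    sequences = {**genome.sequences, **organelle}
    reads = simulate_pool_reads(
        sequences,
        clones,
        layout,
        vector,
        index_table,
        read_len=sim.read_len,
        frag_mean=sim.frag_mean,
        frag_sd=sim.frag_sd,
        depth_per_pool=sim.depth_per_pool,
        error_rate=sim.error_rate,
        host_fraction=sim.host_fraction,
        host_genome=host_genome,
        seed=config.seed + 5,
    )
    truth = build_truth_tables(clones, sequences, sim.bes_truth_len, reads.per_pool_fragments)
    logger.info(
        "simulate: %d clones, %d+%d read pairs (X+Y)",
        len(clones),
        len(reads.reads["X"]),
        len(reads.reads["Y"]),
    )
    return SimulationBundle(
        genome=genome,
        organelle=organelle,
        host_genome=host_genome,
        vector=vector,
        index_table=index_table,
        truth=truth,
        reads=reads,
    )


def stage_preprocess(
    reads: list[io.ReadPair],
    index_table: dict[PoolRef, str],
    host_genome: str,
    config: RunConfig,
) -> tuple[dict[PoolRef, PoolReadSet], int, pd.DataFrame]:
    """Demultiplex by index, quality-filter, and screen out host pairs."""
    pre = config.preprocess
    pools, unassigned = demultiplex(reads, index_table, pre.max_mismatch)
    host_index = build_host_index(host_genome, pre.host_k)
    out: dict[PoolRef, PoolReadSet] = {}
    rows = []
    for pool in sorted(pools):
        prs = quality_trim(pools[pool], pre.min_mean_q, pre.min_len)
        prs = filter_host(prs, host_index, pre.host_k, pre.host_hit_fraction)
        out[pool] = prs
        rows.append(
            {
                "pool_axis": pool.axis.value,
                "pool_index": pool.index,
                "raw": prs.n_raw,
                "after_qc": prs.n_after_qc,
                "valid": prs.n_valid,
            }
        )
    accounting = pd.DataFrame(rows)
    logger.info(
        "preprocess: %d pairs raw, %d valid, %d unassigned",
        accounting["raw"].sum(),
        accounting["valid"].sum(),
        len(unassigned),
    )
    return out, len(unassigned), accounting


def stage_bes_short(
    pools: dict[PoolRef, PoolReadSet], vector: VectorModel, config: RunConfig
) -> list[ShortBes]:
    cfg = config.bes_short
    out: list[ShortBes] = []
    for pool in sorted(pools):
        jrs = find_junction_reads(pools[pool], vector, cfg.min_vector_anchor)
        consensi = cluster_and_consensus(
            jrs, cfg.min_overlap, cfg.min_identity, cfg.min_depth
        )
        for cons in consensi:
            bes = trim_to_bes(cons, vector, cfg.min_vector_anchor)
            if bes is not None:
                out.append(bes)
    logger.info("bes_short: %d short BESs", len(out))
    return out


def stage_bes_long(
    pools: dict[PoolRef, PoolReadSet], vector: VectorModel, config: RunConfig
) -> tuple[list[LongBes], pd.DataFrame]:
    cfg = config.bes_long
    out: list[LongBes] = []
    rows = []
    for pool in sorted(pools):
        contigs = assemble_pool(pools[pool], cfg.min_overlap, cfg.min_identity)
        out.extend(extract_long_bes(contigs, vector, cfg.min_vector_anchor))
        lengths = [len(c.seq) for c in contigs]
        rows.append(
            {
                "pool_axis": pool.axis.value,
                "pool_index": pool.index,
                "n_contigs": len(contigs),
                "n50": n50(lengths) if lengths else 0,
            }
        )
    logger.info("bes_long: %d long BESs", len(out))
    return out, pd.DataFrame(rows)


def stage_assign(
    short_bes: list[ShortBes],
    long_bes: list[LongBes],
    layout: SuperpoolLayout,
    config: RunConfig,
) -> tuple[dict[Source, dict], dict[Source, int]]:
    """Run the four independent deconvolution flows (source x end)."""
    cfg = config.assign
    assignments: dict[Source, dict] = {}
    n_filtered: dict[Source, int] = {}
    for source, bes_list in ((Source.SHORT, short_bes), (Source.LONG, long_bes)):
        flows = []
        filtered = 0
        for end in (End.FORWARD, End.REVERSE):
            rows = [b for b in bes_list if b.end is end and b.pool.axis is Axis.ROW]
            cols = [b for b in bes_list if b.end is end and b.pool.axis is Axis.COL]
            matches = match_pools(rows, cols, layout, cfg.min_identity, cfg.min_cov)
            resolved, nf = resolve_conflicts(
                matches,
                end,
                source,
                policy=Policy(cfg.policy),
                max_wells_per_bes=cfg.max_wells_per_bes,
            )
            flows.append(resolved)
            filtered += nf
        assignments[source] = merge_assignments(flows)
        n_filtered[source] = filtered
        logger.info(
            "assign[%s]: %d wells with BES, %d matches filtered",
            source.value,
            len(assignments[source]),
            filtered,
        )
    return assignments, n_filtered


def _well_candidates(
    assignments: dict, index: GenomeIndex, config: RunConfig, discards: Counter
) -> dict:
    """Single-hit placements per well and end, after optional masking and culling."""
    cfg = config.genmap
    out: dict = {}
    for well, items in assignments.items():
        per_end: dict[End, list] = {}
        for bes in items:
            seq = bes.seq
            if cfg.mask:
                seq = mask_repeats(seq, index, cfg.mask_max_freq)
            hits = align_bes(
                seq,
                index,
                min_identity=cfg.min_identity,
                min_qcov=cfg.min_qcov,
                query_id=bes.bes_id,
            )
            hc = cull_and_classify(hits, cfg.culling_overlap)
            if hc.classification is HitClassification.SINGLE:
                per_end.setdefault(bes.end, []).append((bes.seq, hc.hits[0]))
            elif hc.classification is HitClassification.MULTI:
                discards["MULTI_HIT"] += 1
            else:
                discards["NO_HIT"] += 1
        if per_end:
            out[well] = per_end
    return out


def stage_map(
    assignments: dict[Source, dict],
    sim: SimulationBundle,
    layout: SuperpoolLayout,
    config: RunConfig,
) -> tuple[list[MappedClone], list[OrganelleCall], Counter]:
    cfg = config.genmap
    index = GenomeIndex.from_genome(sim.genome, cfg.seed_k)
    discards: Counter = Counter()

    merged_assignments = merge_assignments(list(assignments.values()))
    organelle_calls = (
        screen_organelle(
            merged_assignments,
            sim.organelle,
            min_identity=cfg.min_identity,
            min_qcov=cfg.min_qcov,
            seed_k=cfg.seed_k,
            nuclear_index=index,
        )
        if sim.organelle
        else []
    )

    placed: dict[Source, dict] = {}
    for source in (Source.SHORT, Source.LONG):
        cands = _well_candidates(assignments.get(source, {}), index, config, discards)
        placed[source], d = pair_and_place(cands, cfg.max_span, source)
        discards.update(d)

    def seq_map(source: Source) -> dict:
        out: dict = {}
        for well, items in assignments.get(source, {}).items():
            per_end: dict[End, list[str]] = {}
            for bes in items:
                per_end.setdefault(bes.end, []).append(bes.seq)
            out[well] = per_end
        return out

    final, d = integrate(
        placed[Source.SHORT],
        placed[Source.LONG],
        seq_map(Source.SHORT),
        seq_map(Source.LONG),
        cfg.min_agreement_identity,
    )
    discards.update(d)
    logger.info(
        "map: %d clones placed (%d paired), %d organelle calls",
        len(final),
        sum(c.evidence.value == "PAIRED" for c in final),
        len(organelle_calls),
    )
    return final, organelle_calls, discards


def stage_gaps(
    final_clones: list[MappedClone], genome: SyntheticGenome, config: RunConfig
) -> tuple[list[GapInterval], list[GapInterval], CoverageReport, InsertStats | None]:
    gaps = find_gaps(genome, config.gaps.min_run)
    coverage = chromosome_coverage(final_clones, genome, gaps)
    covered = covered_gaps(final_clones, gaps)
    paired = [c for c in final_clones if c.evidence.value == "PAIRED"]
    inserts = insert_stats(paired) if paired else None
    logger.info("gaps: %d/%d gaps covered", len(covered), len(gaps))
    return gaps, covered, coverage, inserts


def run_pipeline(
    config: RunConfig, outdir: str | Path | None = None, write_reads: bool = False
) -> PipelineResult:
    """Execute the full pipeline on a simulated superpool.

    When ``outdir`` is given, every stage writes its plain-text artifacts
    there (``write_reads`` additionally dumps the simulated FASTQ).
    Rerunning with the same configuration reproduces identical artifacts.
    """
    layout = config.layout.build()
    sim = stage_simulate(config)
    all_reads = sim.reads.reads["X"] + sim.reads.reads["Y"]
    pools, n_unassigned, accounting = stage_preprocess(
        all_reads, sim.index_table, sim.host_genome, config
    )
    short_bes = stage_bes_short(pools, sim.vector, config)
    long_bes, pool_n50 = stage_bes_long(pools, sim.vector, config)
    assignments, n_filtered = stage_assign(short_bes, long_bes, layout, config)
    final, organelle_calls, discards = stage_map(assignments, sim, layout, config)
    gaps, covered, coverage, inserts = stage_gaps(final, sim.genome, config)

    result = PipelineResult(
        config=config,
        layout=layout,
        sim=sim,
        pools=pools,
        n_unassigned=n_unassigned,
        accounting=accounting,
        short_bes=short_bes,
        long_bes=long_bes,
        pool_n50=pool_n50,
        assignments=assignments,
        n_filtered=n_filtered,
        discards=discards,
        final_clones=final,
        organelle_calls=organelle_calls,
        gaps=gaps,
        covered=covered,
        coverage=coverage,
        inserts=inserts,
    )
    result.summary = build_summary(result)
    if outdir is not None:
        write_artifacts(result, Path(outdir), write_reads=write_reads)
    return result


def build_summary(result: PipelineResult) -> dict:
    """Flat run summary mirroring the pool/assignment/coverage accounting."""
    layout = result.layout
    stats = {
        source: assignment_stats(result.assignments.get(source, {}), layout, source)
        for source in (Source.SHORT, Source.LONG)
    }
    paired = [c for c in result.final_clones if c.evidence.value == "PAIRED"]
    organelle_wells = {c.well for c in result.organelle_calls}
    placed_wells = {c.well for c in result.final_clones}
    summary = {
        "n_wells": layout.n_wells,
        "n_row_pools": layout.n_row_pools,
        "n_col_pools": layout.n_col_pools,
        "n_secondary_pools": layout.n_secondary_pools,
        "clones_per_row_pool": layout.well_cols * layout.plate_grid_cols,
        "clones_per_col_pool": layout.well_rows * layout.plate_grid_rows,
        "effective_clone_size_kb": effective_clone_size_kb(
            result.config.simulate.insert_mean / 1000.0,
            result.sim.vector.backbone_length / 1000.0,
        ),
        "read_pairs_raw": int(result.accounting["raw"].sum()),
        "read_pairs_valid": int(result.accounting["valid"].sum()),
        "read_pairs_unassigned": result.n_unassigned,
        "n_short_bes": len(result.short_bes),
        "n_long_bes": len(result.long_bes),
        "wells_with_short_forward": stats[Source.SHORT].wells_with_forward,
        "wells_with_short_reverse": stats[Source.SHORT].wells_with_reverse,
        "wells_with_short_pair": stats[Source.SHORT].wells_with_pair,
        "wells_with_long_forward": stats[Source.LONG].wells_with_forward,
        "wells_with_long_reverse": stats[Source.LONG].wells_with_reverse,
        "wells_with_long_pair": stats[Source.LONG].wells_with_pair,
        "clones_placed": len(result.final_clones),
        "clones_placed_paired": len(paired),
        "organelle_wells": len(organelle_wells),
        "wells_resolved": len(placed_wells | organelle_wells),
        "n_gaps": len(result.gaps),
        "n_gaps_covered": len(result.covered),
        "coverage_fraction": round(result.coverage.coverage_fraction, 4)
        if result.coverage
        else 0.0,
        "insert_mean_bp": round(result.inserts.mean, 1) if result.inserts else 0.0,
        "insert_sd_bp": round(result.inserts.sd, 1) if result.inserts else 0.0,
    }
    for reason, count in sorted(result.discards.items()):
        summary[f"discard_{reason}"] = count
    return summary


def write_artifacts(result: PipelineResult, outdir: Path, write_reads: bool = False) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    sim = result.sim
    layout = result.layout
    io.write_fasta(sim.genome.sequences, outdir / "genome.fasta")
    io.write_fasta(sim.organelle, outdir / "organelle.fasta")
    io.write_fasta({"host": sim.host_genome}, outdir / "host.fasta")
    io.write_fasta(
        {"left_flank": sim.vector.left_flank, "right_flank": sim.vector.right_flank},
        outdir / "vector.fasta",
    )
    io.write_index_table(sim.index_table, outdir / "index_table.tsv")
    io.write_bed(
        [(g.chrom, g.start, g.end) for g in result.gaps], outdir / "gaps.bed"
    )
    if write_reads:
        for lib in ("X", "Y"):
            io.write_fastq_pairs(
                sim.reads.reads[lib],
                outdir / f"library_{lib}_R1.fastq",
                outdir / f"library_{lib}_R2.fastq",
            )
    truth_rows = [
        {
            "clone_id": c.clone_id,
            "well": layout.well_label(c.well),
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "strand": c.strand,
            "source": c.source.value,
        }
        for c in sim.truth.clones
    ]
    pd.DataFrame(truth_rows).to_csv(outdir / "truth_clones.tsv", sep="\t", index=False)
    io.write_fasta(
        [
            (f"{c.clone_id}|{tag}", seq)
            for c in sim.truth.clones
            for tag, seq in zip(("F", "R"), sim.truth.expected_bes[c.clone_id])
        ],
        outdir / "truth_expected_bes.fasta",
    )
    result.accounting.to_csv(outdir / "pool_accounting.tsv", sep="\t", index=False)
    io.write_fasta(
        [
            (f"SHORT|{b.pool.axis.value}|{b.pool.index}|{b.end.value}|{k}|support={b.support}", b.seq)
            for k, b in enumerate(result.short_bes)
        ],
        outdir / "short_bes.fasta",
    )
    io.write_fasta(
        [
            (f"LONG|{b.pool.axis.value}|{b.pool.index}|{b.end.value}|{k}|contig={b.contig_id}", b.seq)
            for k, b in enumerate(result.long_bes)
        ],
        outdir / "long_bes.fasta",
    )
    result.pool_n50.to_csv(outdir / "pool_n50.tsv", sep="\t", index=False)
    assign_rows = [
        {
            "well": layout.well_label(bes.well),
            "end": bes.end.value,
            "source": bes.source.value,
            "status": bes.status.value,
            "bes_id": bes.bes_id,
            "length": len(bes.seq),
            "seq": bes.seq,
        }
        for source in (Source.SHORT, Source.LONG)
        for items in result.assignments.get(source, {}).values()
        for bes in items
    ]
    pd.DataFrame(
        assign_rows,
        columns=["well", "end", "source", "status", "bes_id", "length", "seq"],
    ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    write_gff3(result.final_clones, outdir / "clones.gff3", layout)
    organelle_rows = [
        {
            "well": layout.well_label(c.well),
            "target": c.target.value,
            "organelle": c.organelle,
            "ends": ",".join(e.value for e in c.ends),
            "paired": c.paired,
            "nuclear_also": c.nuclear_also,
        }
        for c in result.organelle_calls
    ]
    pd.DataFrame(
        organelle_rows,
        columns=["well", "target", "organelle", "ends", "paired", "nuclear_also"],
    ).to_csv(outdir / "organelle_calls.tsv", sep="\t", index=False)
    if result.coverage is not None:
        result.coverage.to_dataframe().to_csv(
            outdir / "coverage_report.tsv", sep="\t", index=False
        )
    pd.DataFrame(
        [{"key": k, "value": v} for k, v in result.summary.items()]
    ).to_csv(outdir / "summary.tsv", sep="\t", index=False)
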