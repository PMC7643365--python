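"""End-to-end orchestration of the sex-linked-region scan on a cohort.

The default study design mirrors a six-population wild cohort with 10 males
and 10 females per population resequenced at 10x, over a compact ~5-Mb
genome (two autosomes and one XY pair). The sex chromosome carries a
20-kb Y-specific insertion, a 10-kb Y-derived repeat duplicated to an
autosome, a 40-kb X-Y diverged region segregating five distinct Y
haplotypes, and a 40-kb X-hemizygous region. k-mer pools use 5 males and
5 females per population.

`run_end_to_end` executes every stage — coverage scan, SNP scan, y-mer
discovery/assembly/placement, candidate calling — and evaluates the calls
against the planted truth.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import caller, covscan, snpstat, ymer
from .formats import CoverageTrack, GenotypeMatrix, SampleTable
from .simdata import (ReadPairs, RegionKind, RegionSpec, SimConfig, SimSystem,
                      simulate_reads, simulate_system)

log = logging.getLogger(__name__)


def default_config(seed: int = 0, with_swept_y: bool = False) -> SimConfig:
    """The default six-population synthetic study system."""
    regions = [
        RegionSpec(400_000, 420_000, RegionKind.Y_SPECIFIC),
        RegionSpec(600_000, 610_000, RegionKind.DUP_REPEAT,
                   dup_targets=[("chr1", 500_000)]),
        RegionSpec(800_000, 840_000, RegionKind.Y_DIVERGED_MULTIHAP,
                   n_y_haplotypes=5, divergence=0.02),
        RegionSpec(1_500_000, 1_540_000, RegionKind.X_HEMIZYGOUS),
    ]
    if with_swept_y:
        regions.insert(3, RegionSpec(1_200_000, 1_240_000, RegionKind.Y_SWEPT,
                                     divergence=0.1))
    return SimConfig(seed=seed, region_specs=regions)


def default_covscan_config(sim: SimConfig) -> covscan.CovScanConfig:
    """Coverage-scan settings matched to the simulator's bin size."""
    return covscan.CovScanConfig(bin_size=sim.coverage_bin,
                                 smooth_len=sim.coverage_bin)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_coverage_scan(system: SimSystem, track: CoverageTrack | None = None,
                      window_size: int = 10_000) -> pd.DataFrame:
    """Coverage scan on the system's (or a supplied) raw coverage track."""
    from .simdata import coverage_from_system

    track = track or coverage_from_system(system)
    cfg = default_covscan_config(system.config)
    return covscan.scan_coverage(track, system.sample_table, cfg, window_size)


def run_snp_scan(system: SimSystem, matrix: GenotypeMatrix | None = None,
                 window_size: int = 10_000) -> pd.DataFrame:
    """Site filtering + windowed statistics + outlier flags per population."""
    from .simdata import genotypes_from_system

    matrix = matrix or genotypes_from_system(system)
    filtered = snpstat.filter_sites(matrix, system.sample_table,
                                    snpstat.SiteFilterConfig())
    stats = snpstat.compute_window_stats(filtered, system.sample_table,
                                         system.config.lengths, window_size)
    stats["da_outlier"] = snpstat.call_outliers(stats, "da")
    stats["fst_outlier"] = snpstat.call_outliers(stats, "fst_mf")
    stats["fis_m_outlier"] = snpstat.call_outliers(stats, "fis_m", direction="low")
    return stats


def _pooled_reads(system: SimSystem, ids: list[str]) -> ReadPairs:
    parts = [simulate_reads(system, s) for s in ids]
    return ReadPairs(np.vstack([p.r1 for p in parts]),
                     np.vstack([p.r2 for p in parts]), "+".join(ids))


@dataclass
class YmerResult:
    ymers: ymer.YmerSet
    filtered_matrix: ymer.KmerCountMatrix
    contigs: dict[str, list[str]]       # population -> contigs
    placements: pd.DataFrame            # with 'population' column
    recruitment: pd.DataFrame


def run_ymer_analysis(system: SimSystem, k: int = 31, pool_males: int = 5,
                      pool_females: int = 5, assembly_k: int = 31,
                      min_unitig_cov: int = 3) -> YmerResult:
    """Streamed conserved-y-mer discovery, assembly, and placement.

    Pooled-sample counting streams against a shrinking candidate set (the
    first male pool is counted in full; later samples only over candidates
    that are still present in every male pool and <= 1 in every female
    pool seen so far), which reproduces the female-filtered master-matrix
    rows exactly without materializing the matrix. Read pools regenerate
    deterministically, so reads are never cached between passes.
    """
    cfg = system.config
    table = system.sample_table
    pops = cfg.populations
    pools = {
        pop: (table.members(pop, "M")[:pool_males],
              table.members(pop, "F")[:pool_females])
        for pop in pops
    }

    # --- streamed counting: male pools first, then female pools
    cand: np.ndarray | None = None
    counts: dict[tuple[str, str], np.ndarray] = {}
    for pop in pops:
        reads = _pooled_reads(system, pools[pop][0])
        stacked = np.vstack([reads.r1, reads.r2])
        del reads
        if cand is None:
            kc = ymer.count_kmers(stacked, k)
            cand = kc.codes
            counts[(pop, "M")] = kc.counts
        else:
            c = ymer.count_in_set(stacked, k, cand)
            keep = c >= 1
            cand = cand[keep]
            counts = {key: v[keep] for key, v in counts.items()}
            counts[(pop, "M")] = c[keep]
        del stacked
        log.info("ymer: %s male pool counted, %d candidate k-mers", pop, len(cand))
    for pop in pops:
        reads = _pooled_reads(system, pools[pop][1])
        stacked = np.vstack([reads.r1, reads.r2])
        del reads
        c = ymer.count_in_set(stacked, k, cand)
        keep = c <= 1
        cand = cand[keep]
        counts = {key: v[keep] for key, v in counts.items()}
        counts[(pop, "F")] = c[keep]
        del stacked
        log.info("ymer: %s female pool counted, %d candidate k-mers", pop, len(cand))

    filtered = ymer.KmerCountMatrix(
        k, cand, np.column_stack([counts[key] for key in sorted(counts)]),
        sorted(counts))
    filtered = ymer.female_filter(filtered)  # idempotent: asserts the rule
    ymers = ymer.call_conserved_ymers(filtered)
    log.info("ymer: %d conserved y-mers", len(ymers))

    # --- selection, assembly, placement per population
    index = ymer.ReferenceIndex.build(system.reference)
    contigs: dict[str, list[str]] = {}
    place_frames = []
    for pop in pops:
        # y-mers have count 0 in every female pool, so only male reads can
        # contain one; scanning male pools suffices.
        reads = _pooled_reads(system, pools[pop][0])
        mask = ymer.select_ymer_reads(reads.r1, reads.r2, ymers)
        sel = np.vstack([reads.r1[mask], reads.r2[mask]])
        del reads
        ctg = ymer.assemble_contigs(sel, assembly_k, min_unitig_cov)
        contigs[pop] = ctg
        placed = ymer.place_contigs(ctg, index)
        placed["population"] = pop
        place_frames.append(placed)
        log.info("ymer: %s — %d reads selected, %d contigs, %d placed",
                 pop, int(mask.sum()), len(ctg),
                 int(placed["chrom"].notna().sum()))
    placements = pd.concat(place_frames, ignore_index=True) if place_frames \
        else pd.DataFrame()
    recruitment = ymer.recruitment_by_window(placements, cfg.lengths)
    return YmerResult(ymers, filtered, contigs, placements, recruitment)


# ---------------------------------------------------------------------------
# evidence assembly + calling
# ---------------------------------------------------------------------------

def evidence_tables(cov_scan: pd.DataFrame, snp_scan: pd.DataFrame,
                    placements: pd.DataFrame, chrom_lengths: dict[str, int],
                    window_size: int = 10_000,
                    fst_threshold: float = 0.3) -> dict[str, pd.DataFrame]:
    """Wide per-population boolean window tables for the caller."""
    out: dict[str, pd.DataFrame] = {}

    cov = cov_scan.copy()
    cov["male"] = cov["cov_class"] == "male_biased"
    cov["female"] = cov["cov_class"] == "female_biased"
    out["coverage_male_bias"] = caller.pivot_flags(cov, "male")
    out["coverage_female_bias"] = caller.pivot_flags(cov, "female")

    snp = snp_scan.copy()
    out["da_outlier"] = caller.pivot_flags(snp, "da_outlier")
    snp["fst_high"] = snp["fst_mf"] > fst_threshold
    out["fst_gt_0.3"] = caller.pivot_flags(snp, "fst_high")
    if "fis_m_outlier" in snp:
        out["fis_outlier"] = caller.pivot_flags(snp, "fis_m_outlier")

    grid = snpstat.make_windows(chrom_lengths, window_size)
    placed = placements.dropna(subset=["chrom"]) if len(placements) else placements
    rec = grid.copy()
    pops = sorted(placed["population"].unique()) if len(placed) else []
    for pop in pops:
        sub = placed[placed["population"] == pop]
        mid = ((sub["start"] + sub["end"]) // 2).to_numpy()
        chroms = sub["chrom"].to_numpy()
        flag = np.zeros(len(grid), dtype=bool)
        for c, m in zip(chroms, mid):
            hit = (grid["chrom"] == c) & (grid["start"] <= m) & (m < grid["end"])
            flag |= hit.to_numpy()
        rec[pop] = flag
    out["ymer_recruitment"] = rec
    return out


@dataclass
class EndToEndResult:
    system: SimSystem
    cov_scan: pd.DataFrame
    snp_scan: pd.DataFrame
    ymer_result: YmerResult
    candidates: pd.DataFrame
    truth_eval: pd.DataFrame
    timings: dict[str, float] = field(default_factory=dict)


def run_end_to_end(seed: int = 0, config: SimConfig | None = None) -> EndToEndResult:
    """Simulate the default system and run every detection stage."""
    t: dict[str, float] = {}
    t0 = time.perf_counter()
    config = config or default_config(seed)
    system = simulate_system(config)
    t["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    cov = run_coverage_scan(system)
    t["coverage"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    snp = run_snp_scan(system)
    t["snp"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    ym = run_ymer_analysis(system)
    t["ymer"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    evidence = evidence_tables(cov, snp, ym.placements, config.lengths)
    cands = caller.call_candidates(evidence, config.n_populations)
    ev = caller.evaluate_against_truth(cands[cands["tier"] == 1], system.truth)
    t["call"] = time.perf_counter() - t0
    t["total"] = sum(t.values())
    log.info("end-to-end timings: %s", {k: round(v, 1) for k, v in t.items()})
    return EndToEndResult(system, cov, snp, ym, cands, ev, t)
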