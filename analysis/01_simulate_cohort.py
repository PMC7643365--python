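#!/usr/bin/env python
"""Build the default six-population synthetic cohort and record its design.

Emits the sample sheet and the planted-truth BED under results/, plus a
small demonstration of the on-disk formats (VCF, bedGraph, FASTQ) for one
population under scratch/ (they are large and regenerate deterministically).
"""

import argparse
from pathlib import Path

from sexscan import formats, pipeline, simdata

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    results = ROOT / "results"
    scratch = ROOT / "scratch" / "cohort"
    results.mkdir(exist_ok=True)
    scratch.mkdir(parents=True, exist_ok=True)

    config = pipeline.default_config(args.seed)
    system = simdata.simulate_system(config)

    formats.write_sample_sheet(system.sample_table, results / "sample_sheet.tsv")
    simdata.write_truth_bed(system, results / "truth.bed")

    genome = sum(l for _, l in config.chrom_lengths)
    print(f"cohort: {config.n_populations} populations x "
          f"{config.males_per_pop}M/{config.females_per_pop}F, "
          f"{genome/1e6:.1f}-Mb genome, depth {config.depth}x")
    print(f"planted regions on {config.sex_chrom}:")
    for r in config.region_specs:
        print(f"  {r.kind.value:21s} {r.start:>9,}-{r.end:<9,}"
              + (f" -> {r.dup_targets}" if r.dup_targets else ""))

    # on-disk format demonstration (regenerable, kept out of the deliverable)
    gm = simdata.genotypes_from_system(system)
    formats.write_vcf(gm, scratch / "genotypes.vcf")
    track = simdata.coverage_from_system(system)
    sid = system.sample_table.ids[0]
    formats.write_coverage_bedgraph(track, sid, scratch / f"{sid}.bedgraph")
    reads = simdata.simulate_reads(system, sid)
    simdata.write_reads_fastq(reads, scratch / f"{sid}_R1.fastq",
                              scratch / f"{sid}_R2.fastq")
    print(f"\n{gm.n_sites:,} segregating sites -> {scratch/'genotypes.vcf'}")
    print(f"{reads.n_pairs:,} read pairs for {sid} -> {scratch}")
    print(f"truth table -> {results/'truth.bed'}")


if __name__ == "__main__":
    main()
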