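#!/usr/bin/env python
"""Male-specific k-mer (y-mer) discovery, assembly, and placement.

Counts canonical 31-mers in pooled 5-male/5-female samples per population,
female-filters the count matrix, calls conserved y-mers (above the
sample-specific male mean everywhere, zero in all females), selects the
reads carrying them, assembles unitigs, and places the contigs on the
reference. This is the expensive stage (several minutes: it streams ~3 Gbp
of reads). Contigs, placements, and the recruitment table go to results/;
the placement table for the caller also goes to scratch/.
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
    scratch = ROOT / "scratch" / "pipeline"
    results.mkdir(exist_ok=True)
    scratch.mkdir(parents=True, exist_ok=True)

    system = simdata.simulate_system(pipeline.default_config(args.seed))
    ym = pipeline.run_ymer_analysis(system)

    print(f"conserved y-mers: {len(ym.ymers):,}")
    print("sample-specific male cutoffs (mean with 95% CI):")
    print(ym.ymers.cutoffs.round(3).to_string(index=False))

    contigs = {f"{pop}_contig{i}": seq
               for pop, seqs in ym.contigs.items()
               for i, seq in enumerate(seqs)}
    formats.write_fasta(contigs, results / "male_specific_contigs.fasta")

    placed = ym.placements.dropna(subset=["chrom"]).copy()
    placed["name"] = placed["population"]
    placed["score"] = placed["score"].round(1)
    formats.write_bed(placed, results / "contig_placements.bed")
    ym.placements.to_csv(scratch / "contig_placements.tsv", sep="\t", index=False)
    formats.write_windows_tsv(ym.recruitment, results / "ymer_recruitment_100kb.tsv")

    print("\ncontigs per population (placed/total):")
    for pop, seqs in ym.contigs.items():
        n_placed = int((placed["population"] == pop).sum())
        total = sum(len(s) for s in seqs)
        print(f"  {pop}: {n_placed}/{len(seqs)} placed, {total:,} bp")
    print("\n100-kb windows with contigs in all populations:")
    pops = system.config.populations
    rec = ym.recruitment
    allpop = rec[(rec[pops] > 0).all(axis=1)]
    print(allpop[["chrom", "start", "end"] + pops].to_string(index=False))


if __name__ == "__main__":
    main()
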