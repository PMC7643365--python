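#!/usr/bin/env python
"""Intersect the three evidence tracks across populations and call
candidate sex-linked regions.

Reads the window tables written by 02/03/04 from scratch/ (run those
first), applies the tier logic — tier 1 = (male-biased coverage AND contig
recruitment in all populations) OR consistent D_a outlier — and evaluates
the calls against the planted truth.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from sexscan import caller, formats, pipeline, simdata

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    results = ROOT / "results"
    scratch = ROOT / "scratch" / "pipeline"
    needed = ["coverage_windows.tsv", "snp_windows.tsv", "contig_placements.tsv"]
    missing = [n for n in needed if not (scratch / n).exists()]
    if missing:
        sys.exit(f"missing {missing}: run analysis/02..04 first")

    system = simdata.simulate_system(pipeline.default_config(args.seed))
    cov = formats.read_windows_tsv(scratch / "coverage_windows.tsv")
    snp = formats.read_windows_tsv(scratch / "snp_windows.tsv")
    for col in ("da_outlier", "fst_outlier", "fis_m_outlier"):
        snp[col] = snp[col].astype(bool)
    placements = pd.read_csv(scratch / "contig_placements.tsv", sep="\t")

    evidence = pipeline.evidence_tables(cov, snp, placements,
                                        system.config.lengths)
    cands = caller.call_candidates(evidence, system.config.n_populations)
    ev = caller.evaluate_against_truth(cands[cands["tier"] == 1], system.truth)

    out = cands.copy()
    out["name"] = out["evidence"]
    out["score"] = out["n_populations_supporting"]
    formats.write_bed(out, results / "candidate_regions.bed")
    formats.write_windows_tsv(cands, results / "candidate_regions.tsv")
    formats.write_windows_tsv(ev.round(3), results / "truth_evaluation.tsv")

    print("candidate regions:")
    print(cands.to_string(index=False))
    print("\nevaluation against planted truth (tier 1):")
    print(ev.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
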