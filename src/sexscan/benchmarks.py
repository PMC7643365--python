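"""Analytic and simulated checkpoint configurations.

These are the small, fully specified scenarios whose expected outcomes are
known in closed form (or to first order): the canonical fully sex-linked
genotype configuration, coverage tracks with a depth-doubled region, and a
uniform-coverage individual for the RPGC normalization identity. They are
used by the acceptance script and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import covscan, snpstat
from .formats import CoverageTrack, SampleTable


def fully_linked_fst(n_males: int = 10, n_females: int = 10,
                     n_sites: int = 50) -> float:
    """Between-sex window F_ST when every male is heterozygous and every
    female homozygous-reference at every site (expected ~1/3)."""
    gt_m = np.ones((n_sites, n_males), dtype=np.int8)
    gt_f = np.zeros((n_sites, n_females), dtype=np.int8)
    return snpstat.fst_between_sexes(gt_m, gt_f)


def _gamma_track(rng: np.random.Generator, mean: np.ndarray,
                 phi: float) -> np.ndarray:
    return rng.gamma(1.0 / phi, phi * mean)


def coverage_ratio_benchmark(rng: np.random.Generator, male_region_depth: float,
                             female_region_depth: float, base_depth: float = 10.0,
                             region_len: int = 1_000_000,
                             background_len: int = 199_000_000,
                             bin_size: int = 1_000, window: int = 10_000,
                             phi: float = 0.05,
                             n_per_sex: int = 10) -> tuple[float, int]:
    """Mean per-window log2(male/female) normalized coverage ratio over a
    1-Mb depth-biased region.

    The region sits next to a large equal-coverage background chromosome —
    as a sex-linked region does in a real genome — so each individual's
    RPGC factor is anchored by the background and a doubled region depth
    maps to a log2 ratio of ~1 rather than being normalized away.
    Returns (mean ratio, number of windows averaged).
    """
    samples = [f"M{i}" for i in range(n_per_sex)] + \
              [f"F{i}" for i in range(n_per_sex)]
    table = SampleTable(pd.DataFrame({
        "id": samples,
        "sex": ["M"] * n_per_sex + ["F"] * n_per_sex,
        "population": "pop1",
    }))
    lengths = {"background": background_len, "region": region_len}
    data = {}
    for chrom, length in lengths.items():
        n_bins = length // bin_size
        mean = np.empty((n_bins, len(samples)))
        for j, s in enumerate(samples):
            if chrom == "region":
                depth = male_region_depth if s.startswith("M") \
                    else female_region_depth
            else:
                depth = base_depth
            mean[:, j] = depth
        data[chrom] = _gamma_track(rng, mean, phi)
    track = CoverageTrack(bin_size, samples, lengths, data)
    normalized = covscan.normalize_rpgc(track)
    windows = covscan.window_means(normalized, window)
    region = windows[windows["chrom"] == "region"]
    ratio = covscan.sex_log2_ratio(region, table, "pop1")
    return float(ratio.mean()), int(len(region))


def rpgc_median_benchmark(rng: np.random.Generator, depth: float = 10.0,
                          length: int = 2_000_000, bin_size: int = 1_000,
                          phi: float = 0.05) -> tuple[float, int]:
    """Median normalized bin value for one uniform-coverage individual
    (expected ~1). Returns (median, number of bins)."""
    n_bins = length // bin_size
    data = {"chr1": _gamma_track(rng, np.full((n_bins, 1), depth), phi)}
    track = CoverageTrack(bin_size, ["ind1"], {"chr1": length}, data)
    normalized = covscan.normalize_rpgc(track)
    return float(np.median(normalized.data["chr1"])), n_bins
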