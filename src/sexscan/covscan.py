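"""Between-sex coverage scan: normalize, trim, filter, window, classify.

The scan mirrors a standard short-read depth workflow: per-individual binned
depth is smoothed (centered moving average), scaled RPGC-style so the
genome-wide expectation is 1x, chromosome ends are trimmed, bins with
normalized coverage above a cutoff (collapsed repeats) are masked, bins are
aggregated into windows by length-weighted mean, and each window gets a
per-population log2(male/female) ratio classified against fixed cutoffs.

A window where the female mean is zero but the male mean is positive is the
Y-specific case of interest; it is assigned +inf and classified male-biased
rather than shrunk with a pseudocount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import CoverageTrack, SampleTable

log = logging.getLogger(__name__)


@dataclass
class CovScanConfig:
    trim_bp: int = 100_000          # trimmed from each chromosome end
    bin_size: int = 50
    smooth_len: int = 75            # centered moving-average width (bp)
    max_norm_cov: float = 4.0       # bins above this are masked
    window_sizes: list[int] = field(default_factory=lambda: [1_000, 10_000])
    log2_male_bias: float = 0.75
    log2_female_bias: float = -0.75
    effective_genome_size: int | None = None

    def __post_init__(self) -> None:
        if not (self.log2_male_bias > 0 > self.log2_female_bias):
            raise ValueError("need log2_male_bias > 0 > log2_female_bias")
        if self.bin_size > self.smooth_len:
            raise ValueError("bin_size must be <= smooth_len")


# ---------------------------------------------------------------------------
# per-track operations
# ---------------------------------------------------------------------------

def smooth_track(track: CoverageTrack, smooth_len: int) -> CoverageTrack:
    """Centered moving average of width smooth_len (floored to an odd
    number of whole bins; widths under 3 bins are a no-op)."""
    width = max(1, int(smooth_len // track.bin_size))
    if width % 2 == 0:
        width -= 1
    if width == 1:
        return track.copy()
    out = track.copy()
    kernel = np.ones(width)
    for chrom, arr in out.data.items():
        sm = np.empty_like(arr)
        for j in range(arr.shape[1]):
            col = arr[:, j]
            ok = ~np.isnan(col)
            num = np.convolve(np.where(ok, col, 0.0), kernel, mode="same")
            den = np.convolve(ok.astype(float), kernel, mode="same")
            with np.errstate(invalid="ignore"):
                sm[:, j] = np.where(den > 0, num / den, np.nan)
        out.data[chrom] = sm
    return out


def normalize_rpgc(track: CoverageTrack, effective_genome_size: int | None = None,
                   trim_bp: int = 0) -> CoverageTrack:
    """Scale each individual so genome-wide mean coverage over untrimmed
    bins equals 1 (reads-per-genomic-context style).

    With ``effective_genome_size`` given, the per-individual total signal
    over untrimmed bins is divided by it; the default effective size is the
    untrimmed genome length, making the untrimmed mean exactly 1. The
    operation is idempotent and scale-invariant. An all-zero individual is
    an error.
    """
    out = track.copy()
    n = len(track.samples)
    total = np.zeros(n)
    egs = 0.0
    for chrom, arr in track.data.items():
        lens = track.bin_lengths(chrom)
        length = track.chrom_lengths[chrom]
        untrimmed = _untrimmed_mask(track, chrom, trim_bp)
        ok = ~np.isnan(arr) & untrimmed[:, None]
        total += np.nansum(np.where(ok, arr, 0.0) * lens[:, None], axis=0)
        egs += float(lens[untrimmed].sum()) if length >= 2 * trim_bp else 0.0
    if effective_genome_size is not None:
        egs = float(effective_genome_size)
    if np.any(total <= 0):
        bad = track.samples[int(np.argmin(total))]
        raise ValueError(f"cannot normalize all-zero coverage track ({bad})")
    factor = total / egs
    for chrom in out.data:
        out.data[chrom] = out.data[chrom] / factor[None, :]
    return out


def _untrimmed_mask(track: CoverageTrack, chrom: str, trim_bp: int) -> np.ndarray:
    n_bins = track.data[chrom].shape[0]
    length = track.chrom_lengths[chrom]
    starts = np.arange(n_bins) * track.bin_size
    ends = np.minimum(starts + track.bin_size, length)
    return (starts >= trim_bp) & (ends <= length - trim_bp)


def trim_and_filter(track: CoverageTrack, config: CovScanConfig) -> CoverageTrack:
    """Remove bins overlapping the terminal trim_bp of each chromosome and
    mask bins with normalized coverage strictly above max_norm_cov."""
    out = track.copy()
    for chrom, arr in out.data.items():
        length = track.chrom_lengths[chrom]
        if length < 2 * config.trim_bp:
            log.warning("covscan: %s shorter than 2x trim (%d bp), dropped",
                        chrom, config.trim_bp)
            arr[:] = np.nan
            continue
        untrimmed = _untrimmed_mask(track, chrom, config.trim_bp)
        arr[~untrimmed, :] = np.nan
        with np.errstate(invalid="ignore"):
            arr[arr > config.max_norm_cov] = np.nan
    return out


def window_means(track: CoverageTrack, window_size: int) -> pd.DataFrame:
    """Length-weighted mean of non-missing bins per window.

    Returns a DataFrame with chrom/start/end plus one column per sample;
    windows whose bins are all missing are NaN.
    """
    if window_size % track.bin_size:
        raise ValueError("window_size must be a multiple of bin_size")
    frames = []
    for chrom, arr in track.data.items():
        length = track.chrom_lengths[chrom]
        lens = track.bin_lengths(chrom)
        n_win = -(-length // window_size)
        win_idx = (np.arange(arr.shape[0]) * track.bin_size) // window_size
        ok = ~np.isnan(arr)
        w = np.where(ok, lens[:, None], 0.0)
        num = np.zeros((n_win, arr.shape[1]))
        den = np.zeros((n_win, arr.shape[1]))
        np.add.at(num, win_idx, np.where(ok, arr, 0.0) * w)
        np.add.at(den, win_idx, w)
        with np.errstate(invalid="ignore"):
            vals = np.where(den > 0, num / den, np.nan)
        starts = np.arange(n_win) * window_size
        df = pd.DataFrame(vals, columns=track.samples)
        df.insert(0, "chrom", chrom)
        df.insert(1, "start", starts)
        df.insert(2, "end", np.minimum(starts + window_size, length))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# between-sex ratio
# ---------------------------------------------------------------------------

def sex_log2_ratio(windows: pd.DataFrame, sample_table: SampleTable,
                   population: str) -> pd.Series:
    """Per-window log2(male mean / female mean) for one population.

    Sex means are unweighted means over individuals. Missing when either
    sex mean is missing; +inf when the female mean is zero with positive
    male mean (and -inf for the converse); NaN when both are zero.
    """
    males = sample_table.members(population, "M")
    females = sample_table.members(population, "F")
    if not males or not females:
        raise ValueError(f"population {population!r} lacks one sex")
    m = windows[males].mean(axis=1, skipna=False).to_numpy()
    f = windows[females].mean(axis=1, skipna=False).to_numpy()
    out = np.full(len(m), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        both = ~np.isnan(m) & ~np.isnan(f)
        pos = both & (m > 0) & (f > 0)
        out[pos] = np.log2(m[pos] / f[pos])
        out[both & (f == 0) & (m > 0)] = np.inf
        out[both & (m == 0) & (f > 0)] = -np.inf
    return pd.Series(out, index=windows.index, name=f"log2_ratio_{population}")


def classify_bias(ratio: pd.Series | np.ndarray, config: CovScanConfig) -> pd.Series:
    """male_biased / female_biased / unbiased / missing by strict cutoffs."""
    r = np.asarray(ratio, dtype=float)
    out = np.full(r.shape, "unbiased", dtype=object)
    out[np.isnan(r)] = "missing"
    out[r > config.log2_male_bias] = "male_biased"
    out[r < config.log2_female_bias] = "female_biased"
    return pd.Series(out, index=getattr(ratio, "index", None))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def scan_coverage(track: CoverageTrack, sample_table: SampleTable,
                  config: CovScanConfig, window_size: int = 10_000) -> pd.DataFrame:
    """Full scan: smooth -> normalize -> trim/filter -> window -> ratio/class.

    Returns a long-format table with one row per (window, population):
    chrom, start, end, population, log2_cov_ratio, cov_class.
    """
    smoothed = smooth_track(track, config.smooth_len)
    normalized = normalize_rpgc(smoothed, config.effective_genome_size,
                                trim_bp=config.trim_bp)
    filtered = trim_and_filter(normalized, config)
    windows = window_means(filtered, window_size)
    frames = []
    for pop in sample_table.populations:
        ratio = sex_log2_ratio(windows, sample_table, pop)
        df = windows[["chrom", "start", "end"]].copy()
        df["population"] = pop
        df["log2_cov_ratio"] = ratio.to_numpy()
        df["cov_class"] = classify_bias(ratio, config).to_numpy()
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
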