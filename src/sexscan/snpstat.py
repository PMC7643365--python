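"""Windowed between-sex SNP statistics: pi, D_XY, D_a, F_ST, F_IS.

All statistics are computed per population between (or within) the sexes in
fixed genomic windows, with window length in bp as the denominator for the
per-site quantities, so pi/D_XY/D_a are comparable across windows with
different SNP counts. D_a = D_XY(male, female) - pi(female) is the net
divergence: it responds to an abundance of low-frequency male-specific
variants (many segregating Y haplotypes) that leave F_ST low.

F_ST is the Nei/Chesser (1983) sample-size-corrected G_ST by default, as a
ratio of sums over window sites; under the canonical fully sex-linked
configuration (all males heterozygous, all females homozygous) it gives the
textbook value of 1/3. The Hudson/Bhatia estimator (which gives ~0.5 on the
same configuration) is available as a labeled alternative. Negative
estimates are retained so the null distribution stays intact for outlier
calling. Windows without usable SNPs are reported missing, never zero.

Outliers are windows above the population's genome-wide mean + k*SD
(default k=3); for F_IS the informative direction is a male heterozygote
excess, flagged below mean - k*SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import MISSING, GenotypeMatrix, SampleTable

log = logging.getLogger(__name__)


@dataclass
class SiteFilterConfig:
    min_depth: int = 5
    max_depth: int = 200
    max_missing_frac: float = 0.10
    min_maf: float = 0.05
    require_all_populations: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_depth < self.max_depth:
            raise ValueError("need 0 < min_depth < max_depth")
        if not 0 <= self.max_missing_frac <= 1:
            raise ValueError("max_missing_frac must be in [0, 1]")
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")


@dataclass
class OutlierConfig:
    sd_multiplier: float = 3.0
    min_windows: int = 30
    exclude_chrom: str | None = None

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be > 0")


_EPS = 1e-12


# ---------------------------------------------------------------------------
# site filtering
# ---------------------------------------------------------------------------

def filter_sites(matrix: GenotypeMatrix, sample_table: SampleTable,
                 config: SiteFilterConfig) -> GenotypeMatrix:
    """Apply depth, missingness, and MAF rules; missingness and MAF are
    evaluated per population, and by default a site must pass in every
    population to be retained anywhere."""
    gt = matrix.gt.copy()
    n_depth_masked = 0
    if matrix.depth is not None:
        bad = (matrix.depth < config.min_depth) | (matrix.depth > config.max_depth)
        bad &= gt != MISSING
        n_depth_masked = int(bad.sum())
        gt[bad] = MISSING

    pops = sample_table.populations
    pass_pop = np.ones((matrix.n_sites, len(pops)), dtype=bool)
    fail_missing = np.zeros(len(pops), dtype=int)
    fail_maf = np.zeros(len(pops), dtype=int)
    for p, pop in enumerate(pops):
        ids = sample_table.members(pop, "M") + sample_table.members(pop, "F")
        idx = [matrix.samples.index(i) for i in ids]
        sub = gt[:, idx]
        miss = (sub == MISSING).mean(axis=1)
        ok_miss = miss <= config.max_missing_frac + _EPS
        called = sub != MISSING
        n_alleles = 2 * called.sum(axis=1)
        alt = np.where(called, sub, 0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            p_alt = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
        maf = np.minimum(p_alt, 1 - p_alt)
        ok_maf = (maf >= config.min_maf - _EPS) & (n_alleles > 0)
        pass_pop[:, p] = ok_miss & ok_maf
        fail_missing[p] = int((~ok_miss).sum())
        fail_maf[p] = int((ok_miss & ~ok_maf).sum())

    keep = pass_pop.all(axis=1) if config.require_all_populations else pass_pop.any(axis=1)
    log.info(
        "filter_sites: %d/%d sites kept (%d genotypes depth-masked; "
        "missingness failures per population %s; MAF failures %s)",
        int(keep.sum()), matrix.n_sites, n_depth_masked,
        fail_missing.tolist(), fail_maf.tolist(),
    )
    out = GenotypeMatrix(matrix.sites.loc[keep].reset_index(drop=True), gt[keep],
                         list(matrix.samples),
                         None if matrix.depth is None else matrix.depth[keep])
    return out


# ---------------------------------------------------------------------------
# per-site building blocks (genotype arrays are sites x individuals,
# values 0/1/2 alt dosage, MISSING for no-call)
# ---------------------------------------------------------------------------

def _allele_counts(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n alleles, alt allele count) per site, missing excluded."""
    gt = np.atleast_2d(gt)
    called = gt != MISSING
    n = 2 * called.sum(axis=1)
    j = np.where(called, gt, 0).sum(axis=1)
    return n.astype(float), j.astype(float)


def pi_within(gt: np.ndarray) -> np.ndarray:
    """Unbiased per-site pairwise diversity 2 j (n-j) / (n (n-1)) for j alt
    alleles among n; NaN where fewer than 2 alleles."""
    n, j = _allele_counts(gt)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2 * j * (n - j) / (n * (n - 1))
    pi[n < 2] = np.nan
    return pi


def dxy_between(gt_a: np.ndarray, gt_b: np.ndarray) -> np.ndarray:
    """Per-site mean pairwise difference between groups:
    p_a (1-p_b) + p_b (1-p_a); NaN where either group has no alleles."""
    na, ja = _allele_counts(gt_a)
    nb, jb = _allele_counts(gt_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa, pb = ja / na, jb / nb
    out = pa * (1 - pb) + pb * (1 - pa)
    out[(na < 1) | (nb < 1)] = np.nan
    return out


def da(dxy_mf: float | np.ndarray, pi_f: float | np.ndarray):
    """Net divergence D_a = D_XY - female pi (may be negative)."""
    return dxy_mf - pi_f


def _obs_het(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(observed het fraction, n individuals called) per site."""
    gt = np.atleast_2d(gt)
    called = gt != MISSING
    n_ind = called.sum(axis=1).astype(float)
    het = (gt == 1).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = het / n_ind
    ho[n_ind == 0] = np.nan
    return ho, n_ind


def _nei_chesser_site(gt_m: np.ndarray, gt_f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (Hs_hat, Ht_hat) for two groups, Nei & Chesser (1983)
    sample-size-corrected, k = 2 demes weighted equally."""
    nm, jm = _allele_counts(gt_m)
    nf, jf = _allele_counts(gt_f)
    hom, n_ind_m = _obs_het(gt_m)
    hof, n_ind_f = _obs_het(gt_f)
    with np.errstate(invalid="ignore", divide="ignore"):
        pm, pf = jm / nm, jf / nf
        # harmonic mean of individuals per group
        n_tilde = 2.0 / (1.0 / n_ind_m + 1.0 / n_ind_f)
        msp = ((pm**2 + (1 - pm) ** 2) + (pf**2 + (1 - pf) ** 2)) / 2
        ho_bar = (hom + hof) / 2
        hs = n_tilde / (n_tilde - 1) * (1 - msp - ho_bar / (2 * n_tilde))
        xbar = (pm + pf) / 2
        ht = 1 - (xbar**2 + (1 - xbar) ** 2) + hs / (2 * n_tilde) - ho_bar / (4 * n_tilde)
    bad = (n_ind_m < 2) | (n_ind_f < 2)
    hs[bad] = np.nan
    ht[bad] = np.nan
    return hs, ht


def _hudson_site(gt_m: np.ndarray, gt_f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (numerator, denominator) of the Hudson/Bhatia F_ST."""
    nm, jm = _allele_counts(gt_m)
    nf, jf = _allele_counts(gt_f)
    with np.errstate(invalid="ignore", divide="ignore"):
        pm, pf = jm / nm, jf / nf
        num = (pm - pf) ** 2 - pm * (1 - pm) / (nm - 1) - pf * (1 - pf) / (nf - 1)
        den = pm * (1 - pf) + pf * (1 - pm)
    bad = (nm < 2) | (nf < 2)
    num[bad] = np.nan
    den[bad] = np.nan
    return num, den


def fst_between_sexes(gt_m: np.ndarray, gt_f: np.ndarray,
                      estimator: str = "nei") -> float:
    """Windowed between-sex F_ST over the supplied sites (ratio of sums).

    estimator: "nei" (Nei/Chesser corrected G_ST, default) or "hudson".
    Returns NaN when the total heterozygosity is zero or no usable sites.
    """
    if estimator == "nei":
        hs, ht = _nei_chesser_site(gt_m, gt_f)
        num, den = ht - hs, ht
    elif estimator == "hudson":
        num, den = _hudson_site(gt_m, gt_f)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    ok = ~np.isnan(num) & ~np.isnan(den)
    if not ok.any() or den[ok].sum() <= 0:
        return float("nan")
    return float(num[ok].sum() / den[ok].sum())


def fis_within_sex(gt: np.ndarray) -> float:
    """Window F_IS = 1 - sum(Ho) / sum(He) over sites; He is the unbiased
    gene diversity. Negative values mean heterozygote excess."""
    ho, n_ind = _obs_het(gt)
    n, j = _allele_counts(gt)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = j / n
        he = n / (n - 1) * 2 * p * (1 - p)
    ok = (n >= 2) & ~np.isnan(ho)
    if not ok.any() or he[ok].sum() <= 0:
        return float("nan")
    return float(1 - ho[ok].sum() / he[ok].sum())


# ---------------------------------------------------------------------------
# windowed scan
# ---------------------------------------------------------------------------

def make_windows(chrom_lengths: dict[str, int], window_size: int) -> pd.DataFrame:
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, window_size)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + window_size, length))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def compute_window_stats(matrix: GenotypeMatrix, sample_table: SampleTable,
                         chrom_lengths: dict[str, int], window_size: int = 10_000,
                         estimator: str = "nei") -> pd.DataFrame:
    """Per-window, per-population table of pi_m, pi_f, dxy_mf, da, fst_mf,
    fis_m, fis_f and n_sites. Windows with no usable SNPs are missing."""
    windows = make_windows(chrom_lengths, window_size)
    frames = []
    for pop in sample_table.populations:
        males = sample_table.members(pop, "M")
        females = sample_table.members(pop, "F")
        gm_all = matrix.columns(males)
        gf_all = matrix.columns(females)
        df = windows.copy()
        df["population"] = pop
        cols = {c: np.full(len(windows), np.nan)
                for c in ("pi_m", "pi_f", "dxy_mf", "da", "fst_mf", "fis_m", "fis_f")}
        n_sites = np.zeros(len(windows), dtype=int)
        wgrp = windows.groupby("chrom", sort=False)
        for chrom, wdf in wgrp:
            smask = (matrix.sites["chrom"] == chrom).to_numpy()
            if not smask.any():
                continue
            pos = matrix.sites.loc[smask, "pos"].to_numpy()
            gm = gm_all[smask]
            gf = gf_all[smask]
            widx_local = pos // window_size
            base = wdf.index.to_numpy()  # global window row ids, ordered by start
            pi_m = pi_within(gm)
            pi_f = pi_within(gf)
            dxy = dxy_between(gm, gf)
            usable = ~np.isnan(dxy) & ~np.isnan(pi_m) & ~np.isnan(pi_f)
            if estimator == "nei":
                hs, ht = _nei_chesser_site(gm, gf)
                fnum, fden = ht - hs, ht
            else:
                fnum, fden = _hudson_site(gm, gf)
            ho_m, _ = _obs_het(gm)
            ho_f, _ = _obs_het(gf)
            n_al_m, j_m = _allele_counts(gm)
            n_al_f, j_f = _allele_counts(gf)
            with np.errstate(invalid="ignore", divide="ignore"):
                he_m = n_al_m / (n_al_m - 1) * 2 * (j_m / n_al_m) * (1 - j_m / n_al_m)
                he_f = n_al_f / (n_al_f - 1) * 2 * (j_f / n_al_f) * (1 - j_f / n_al_f)

            def wsum(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
                out = np.zeros(len(wdf))
                m = mask & ~np.isnan(values)
                np.add.at(out, widx_local[m], values[m])
                return out

            lens = (wdf["end"] - wdf["start"]).to_numpy().astype(float)
            cnt = np.zeros(len(wdf))
            np.add.at(cnt, widx_local[usable], 1)
            n_sites[base] = cnt.astype(int)
            has = cnt > 0
            s_pi_m = wsum(pi_m, usable)
            s_pi_f = wsum(pi_f, usable)
            s_dxy = wsum(dxy, usable)
            cols["pi_m"][base[has]] = (s_pi_m / lens)[has]
            cols["pi_f"][base[has]] = (s_pi_f / lens)[has]
            cols["dxy_mf"][base[has]] = (s_dxy / lens)[has]
            cols["da"][base[has]] = ((s_dxy - s_pi_f) / lens)[has]
            s_fnum = wsum(fnum, usable)
            s_fden = wsum(fden, usable)
            okf = has & (s_fden > 0)
            cols["fst_mf"][base[okf]] = (s_fnum[okf] / s_fden[okf])
            for tag, ho, he in (("fis_m", ho_m, he_m), ("fis_f", ho_f, he_f)):
                s_ho = wsum(ho, usable)
                s_he = wsum(he, usable)
                okh = has & (s_he > 0)
                cols[tag][base[okh]] = 1 - s_ho[okh] / s_he[okh]
        for c, v in cols.items():
            df[c] = v
        df["n_sites"] = n_sites
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# outliers
# ---------------------------------------------------------------------------

def call_outliers(window_stats: pd.DataFrame, column: str,
                  config: OutlierConfig | None = None,
                  direction: str = "high") -> pd.Series:
    """Flag windows beyond mean +/- sd_multiplier * SD, computed genome-wide
    per population over non-missing windows. ``direction`` chooses the tail
    ("high" for D_a/F_ST-style outliers, "low" for male F_IS excess)."""
    config = config or OutlierConfig()
    flags = np.zeros(len(window_stats), dtype=bool)
    for pop, grp in window_stats.groupby("population"):
        vals = grp[column]
        base = grp.index
        if config.exclude_chrom is not None:
            vals = vals[grp["chrom"] != config.exclude_chrom]
        ok = vals.dropna()
        if len(ok) < config.min_windows:
            log.warning("call_outliers: only %d non-missing windows for %s in %s",
                        len(ok), column, pop)
        if len(ok) < 2:
            continue
        mu, sd = ok.mean(), ok.std(ddof=1)
        if direction == "high":
            thr = mu + config.sd_multiplier * sd
            flags[base] = (window_stats.loc[base, column] > thr).to_numpy()
        else:
            thr = mu - config.sd_multiplier * sd
            flags[base] = (window_stats.loc[base, column] < thr).to_numpy()
    return pd.Series(flags, index=window_stats.index, name=f"{column}_outlier")
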