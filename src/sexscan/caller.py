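"""Cross-population evidence intersection and candidate region calling.

A window supports a candidate when flagged by a detection track (coverage
bias, D_a outlier, F_ST > 0.3, F_IS outlier, y-mer contig recruitment) in
enough populations. Candidate tiers encode the headline logic:

* tier 1 — (male coverage bias in all populations AND y-mer recruitment in
  all populations) OR (D_a outlier in all populations);
* tier 2 — any single evidence type consistent across all populations.

F_ST > 0.3 windows are carried as supplementary evidence only: between-sex
F_ST is expected to be inconsistent across populations whenever multiple Y
haplotypes segregate. Qualifying windows that are adjacent (or separated by
a single missing window) merge into one reported region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EVIDENCE_TYPES = [
    "coverage_male_bias",
    "coverage_female_bias",
    "da_outlier",
    "fst_gt_0.3",
    "fis_outlier",
    "ymer_recruitment",
]


@dataclass
class CallerConfig:
    min_populations: int | None = None  # default: all populations
    merge_gap_windows: int = 1          # bridge this many missing windows
    fst_threshold: float = 0.3


# ---------------------------------------------------------------------------
# shared windows
# ---------------------------------------------------------------------------

def shared_windows(flags: pd.DataFrame, min_populations: int) -> pd.DataFrame:
    """Count supporting populations per window and retain those with
    support >= min_populations.

    ``flags`` must have chrom/start/end plus one boolean column per
    population. Lowering min_populations never removes a retained window.
    """
    popcols = [c for c in flags.columns if c not in ("chrom", "start", "end")]
    out = flags[["chrom", "start", "end"]].copy()
    out["support"] = flags[popcols].fillna(False).astype(bool).sum(axis=1)
    return out[out["support"] >= min_populations].reset_index(drop=True)


def pivot_flags(long_df: pd.DataFrame, column: str) -> pd.DataFrame:
    """Long (window x population) boolean column -> wide per-population."""
    wide = long_df.pivot_table(index=["chrom", "start", "end"],
                               columns="population", values=column,
                               aggfunc="first")
    wide = wide.fillna(False).astype(bool).reset_index()
    wide.columns.name = None
    return wide


# ---------------------------------------------------------------------------
# candidate calling
# ---------------------------------------------------------------------------

def call_candidates(evidence: dict[str, pd.DataFrame], n_populations: int,
                    config: CallerConfig | None = None) -> pd.DataFrame:
    """Merge per-window cross-population evidence into ranked regions.

    ``evidence`` maps evidence type (EVIDENCE_TYPES) to a wide DataFrame
    (chrom/start/end + one boolean column per population); missing types are
    treated as absent evidence. Output rows: chrom, start, end, tier,
    evidence (comma string), n_populations_supporting (max over types).
    """
    config = config or CallerConfig()
    min_pops = config.min_populations or n_populations

    # union window grid
    grids = [df[["chrom", "start", "end"]] for df in evidence.values()]
    if not grids:
        return pd.DataFrame(columns=["chrom", "start", "end", "tier",
                                     "evidence", "n_populations_supporting"])
    grid = pd.concat(grids).drop_duplicates().sort_values(
        ["chrom", "start"]).reset_index(drop=True)

    support = {}
    for ev in EVIDENCE_TYPES:
        if ev in evidence:
            sw = evidence[ev].copy()
            popcols = [c for c in sw.columns if c not in ("chrom", "start", "end")]
            sw["support"] = sw[popcols].fillna(False).astype(bool).sum(axis=1)
            merged = grid.merge(sw[["chrom", "start", "end", "support"]],
                                on=["chrom", "start", "end"], how="left")
            support[ev] = merged["support"].fillna(0).astype(int).to_numpy()
        else:
            support[ev] = np.zeros(len(grid), dtype=int)

    cov = support["coverage_male_bias"] >= min_pops
    rec = support["ymer_recruitment"] >= min_pops
    da_all = support["da_outlier"] >= min_pops
    tier1 = (cov & rec) | da_all
    any_all = np.zeros(len(grid), dtype=bool)
    for ev in EVIDENCE_TYPES:
        any_all |= support[ev] >= min_pops
    tier = np.where(tier1, 1, np.where(any_all, 2, 0))

    qual = grid.assign(tier=tier)
    qual = qual[qual["tier"] > 0].reset_index(drop=True)
    regions = _merge_windows(qual, gap_windows=config.merge_gap_windows)

    # annotate merged regions with their evidence and support
    out_rows = []
    for row in regions.itertuples(index=False):
        m = (grid["chrom"] == row.chrom) & (grid["start"] < row.end) & (grid["end"] > row.start)
        evs = [ev for ev in EVIDENCE_TYPES if support[ev][m.to_numpy()].max(initial=0) >= min_pops]
        n_sup = max(int(support[ev][m.to_numpy()].max(initial=0)) for ev in EVIDENCE_TYPES)
        out_rows.append((row.chrom, row.start, row.end, row.tier, ",".join(evs), n_sup))
    out = pd.DataFrame(out_rows, columns=["chrom", "start", "end", "tier",
                                          "evidence", "n_populations_supporting"])
    return out.sort_values(["tier", "chrom", "start"]).reset_index(drop=True)


def _merge_windows(qual: pd.DataFrame, gap_windows: int) -> pd.DataFrame:
    """Merge adjacent/book-ended qualifying windows (within tier; a tier-1
    window absorbs overlapping tier-2 neighbours), bridging up to
    ``gap_windows`` missing windows."""
    if qual.empty:
        return qual.copy()
    rows = []
    win = int(np.median(qual["end"] - qual["start"])) if len(qual) else 0
    gap_bp = gap_windows * win
    for chrom, grp in qual.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        cur_s, cur_e, cur_t = None, None, 0
        for r in grp.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e, cur_t = r.start, r.end, r.tier
            elif r.start <= cur_e + gap_bp:
                cur_e = max(cur_e, r.end)
                cur_t = min(cur_t, r.tier)  # best (lowest) tier wins
            else:
                rows.append((chrom, cur_s, cur_e, cur_t))
                cur_s, cur_e, cur_t = r.start, r.end, r.tier
        rows.append((chrom, cur_s, cur_e, cur_t))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tier"])


# ---------------------------------------------------------------------------
# truth evaluation
# ---------------------------------------------------------------------------

def evaluate_against_truth(candidates: pd.DataFrame,
                           truth: pd.DataFrame) -> pd.DataFrame:
    """Interval-overlap (>= 1 bp) precision/recall.

    Returns one row per truth kind with recall, plus an '__overall__' row
    carrying precision (fraction of candidates touching any truth
    interval).
    """
    def overlaps(a: pd.Series, b: pd.DataFrame) -> bool:
        m = (b["chrom"] == a["chrom"]) & (b["start"] < a["end"]) & (b["end"] > a["start"])
        return bool(m.any())

    truth_iv = truth[["chrom", "start", "end", "kind"]].drop_duplicates()
    rows = []
    for kind, grp in truth_iv.groupby("kind"):
        hit = sum(overlaps(t, candidates) for _, t in grp.iterrows())
        rows.append((kind, hit / len(grp), len(grp)))
    if len(candidates):
        prec = np.mean([overlaps(c, truth_iv) for _, c in candidates.iterrows()])
    else:
        prec = float("nan")
    out = pd.DataFrame(rows, columns=["kind", "recall", "n_truth"])
    out = pd.concat([out, pd.DataFrame(
        [("__overall__", float("nan"), len(truth_iv))],
        columns=out.columns)], ignore_index=True)
    out["precision"] = np.nan
    out.loc[out["kind"] == "__overall__", "precision"] = prec
    return out
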