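"""Male-specific k-mer (y-mer) discovery, assembly, and placement.

Workflow (per the canonical k-mer route to sex-linked sequence):

1. Count canonical k-mers per pooled sex-within-population sample.
2. Female-filter the count matrix: keep k-mers with count <= 1 in every
   female column and >= 1 in every male column.
3. Call conserved y-mers: count above the sample-specific male mean in
   every male sample, and exactly 0 in every female sample.
4. Select the read pairs containing y-mers (either mate, either strand).
5. Assemble them with a minimal de Bruijn unitig assembler.
6. Place contigs on the reference by exact k-mer seeding plus edlib
   verification; ties go to the lowest coordinate, which is what sends
   contigs from duplicated Y repeats to their autosomal copies.

k-mers are packed 2 bits/base into uint64 (k <= 31); a canonical k-mer is
min(kmer, revcomp) on the packed codes, which coincides with lexicographic
order on the sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dna

log = logging.getLogger(__name__)

_SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)


# ---------------------------------------------------------------------------
# packed k-mer codes
# ---------------------------------------------------------------------------

def encode_kmer(kmer: str) -> int:
    codes = dna.encode(kmer)
    if np.any(codes >= 4):
        raise ValueError("k-mer contains non-ACGT base")
    out = 0
    for b in codes:
        out = (out << 2) | int(b)
    return out


def decode_kmer(code: int, k: int) -> str:
    bases = []
    for i in range(k):
        bases.append(int(code >> (2 * (k - 1 - i))) & 3)
    return dna.decode(np.array(bases, dtype=np.uint8))


def canonical_code(code: int, k: int) -> int:
    rc = 0
    c = code
    for _ in range(k):
        rc = (rc << 2) | (3 - (c & 3))
        c >>= 2
    return min(code, rc)


def _as_matrix(reads) -> np.ndarray:
    """Accept a uint8 matrix, a list of equal-length strings, or a list of
    uint8 arrays (ragged input is padded with N)."""
    if isinstance(reads, np.ndarray) and reads.ndim == 2:
        return reads
    rows = [dna.encode(r) if isinstance(r, str) else np.asarray(r, dtype=np.uint8)
            for r in reads]
    if not rows:
        return np.zeros((0, 0), dtype=np.uint8)
    width = max(len(r) for r in rows)
    mat = np.full((len(rows), width), dna.N, dtype=np.uint8)
    for i, r in enumerate(rows):
        mat[i, : len(r)] = r
    return mat


def read_kmer_codes(reads, k: int, canonical: bool = True) -> np.ndarray:
    """All (canonical) k-mer codes of a read matrix, invalid positions
    (windows containing N, or rows shorter than k) marked with the sentinel.

    Returns an (n_reads, n_positions) uint64 matrix so callers can reduce
    per read (membership) or flatten (counting).
    """
    mat = _as_matrix(reads)
    n, length = mat.shape
    if length < k or n == 0:
        return np.full((n, 0), _SENTINEL, dtype=np.uint64)
    mask = np.uint64((1 << (2 * k)) - 1)
    shift = np.uint64(2 * (k - 1))
    two = np.uint64(2)
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    since_n = np.zeros(n, dtype=np.int32)
    out = np.empty((n, length - k + 1), dtype=np.uint64)
    for i in range(length):
        b = mat[:, i]
        good = b < 4
        bb = np.where(good, b, 0).astype(np.uint64)
        fwd = ((fwd << two) | bb) & mask
        rc = (rc >> two) | ((np.uint64(3) - bb) << shift)
        since_n = np.where(good, since_n + 1, 0)
        if i >= k - 1:
            col = np.minimum(fwd, rc) if canonical else fwd
            out[:, i - k + 1] = np.where(since_n >= k, col, _SENTINEL)
    return out


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

@dataclass
class KmerCounts:
    """Exact counts for one pooled sample: sorted codes with counts."""

    k: int
    codes: np.ndarray   # sorted uint64
    counts: np.ndarray  # int64, aligned with codes
    canonical: bool = True

    @property
    def n_kmers(self) -> int:
        return len(self.codes)

    def to_dict(self) -> dict[str, int]:
        return {decode_kmer(int(c), self.k): int(n)
                for c, n in zip(self.codes, self.counts)}

    def get(self, kmer: str) -> int:
        code = encode_kmer(kmer)
        if self.canonical:
            code = canonical_code(code, self.k)
        i = np.searchsorted(self.codes, np.uint64(code))
        if i < len(self.codes) and self.codes[i] == np.uint64(code):
            return int(self.counts[i])
        return 0


def flat_kmer_codes(reads, k: int, canonical: bool = True,
                    chunk_reads: int = 200_000):
    """Yield 1D arrays of valid (canonical) k-mer codes per read chunk.

    Position-major layout internally, so writes are contiguous; output
    order is arbitrary, which is fine for counting.
    """
    mat = _as_matrix(reads)
    n_all, length = mat.shape
    if n_all and length < k:
        log.warning("flat_kmer_codes: k=%d exceeds read length %d", k, length)
        return
    mask = np.uint64((1 << (2 * k)) - 1)
    shift = np.uint64(2 * (k - 1))
    two = np.uint64(2)
    for lo in range(0, n_all, chunk_reads):
        sub = mat[lo:lo + chunk_reads]
        n = sub.shape[0]
        has_n = bool((sub >= 4).any())
        fwd = np.zeros(n, dtype=np.uint64)
        rc = np.zeros(n, dtype=np.uint64)
        since_n = np.zeros(n, dtype=np.int32) if has_n else None
        out = np.empty((length - k + 1, n), dtype=np.uint64)
        valid = np.empty((length - k + 1, n), dtype=bool) if has_n else None
        for i in range(length):
            b = sub[:, i]
            if has_n:
                good = b < 4
                bb = np.where(good, b, 0).astype(np.uint64)
                since_n = np.where(good, since_n + 1, 0)
            else:
                bb = b.astype(np.uint64)
            fwd = ((fwd << two) | bb) & mask
            rc = (rc >> two) | ((np.uint64(3) - bb) << shift)
            if i >= k - 1:
                out[i - k + 1] = np.minimum(fwd, rc) if canonical else fwd
                if has_n:
                    valid[i - k + 1] = since_n >= k
        flat = out.ravel()
        if has_n:
            flat = flat[valid.ravel()]
        yield flat


def count_kmers(reads, k: int, canonical: bool = True,
                chunk_reads: int = 200_000) -> KmerCounts:
    """Exact (canonical) k-mer counts over a read set; k-mers containing N
    are skipped. Warns and returns empty counts when k exceeds read length."""
    if k > 31:
        raise ValueError("k must be <= 31 for packed counting")
    chunks = list(flat_kmer_codes(reads, k, canonical, chunk_reads))
    if not chunks:
        return KmerCounts(k, np.zeros(0, np.uint64), np.zeros(0, np.int64), canonical)
    allc = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]
    del chunks
    if len(allc) == 0:
        return KmerCounts(k, allc, np.zeros(0, np.int64), canonical)
    allc.sort()
    edge = np.flatnonzero(np.diff(allc)) + 1
    starts = np.concatenate([[0], edge])
    counts = np.diff(np.concatenate([starts, [len(allc)]])).astype(np.int64)
    return KmerCounts(k, allc[starts].copy(), counts, canonical)


def count_in_set(reads, k: int, codes_sorted: np.ndarray,
                 canonical: bool = True, chunk_reads: int = 200_000) -> np.ndarray:
    """Counts of a fixed sorted code set within a read pool (streaming:
    nothing outside the set is tallied)."""
    out = np.zeros(len(codes_sorted), dtype=np.int64)
    if len(codes_sorted) == 0:
        return out
    for codes in flat_kmer_codes(reads, k, canonical, chunk_reads):
        # sorting the probes makes the binary search cache-friendly
        codes.sort()
        edge = np.flatnonzero(np.diff(codes)) + 1
        starts = np.concatenate([[0], edge]) if len(codes) else np.zeros(0, int)
        uniq = codes[starts] if len(codes) else codes
        cnt = np.diff(np.concatenate([starts, [len(codes)]])) if len(codes) else starts
        idx = np.searchsorted(codes_sorted, uniq)
        idx[idx == len(codes_sorted)] = 0
        hit = codes_sorted[idx] == uniq
        if hit.any():
            out += np.bincount(idx[hit], weights=cnt[hit],
                               minlength=len(codes_sorted)).astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# matrix, female filter, conserved y-mers
# ---------------------------------------------------------------------------

@dataclass
class KmerCountMatrix:
    """Canonical k-mer counts, rows = k-mers, columns = pooled samples
    keyed by (population, sex)."""

    k: int
    codes: np.ndarray                 # sorted uint64
    counts: np.ndarray                # (n_kmers, n_cols) int64
    columns: list[tuple[str, str]]    # (population, sex)
    canonical: bool = True

    @classmethod
    def from_columns(cls, samples: dict[tuple[str, str], KmerCounts]) -> "KmerCountMatrix":
        cols = sorted(samples)
        ks = {s.k for s in samples.values()}
        if len(ks) != 1:
            raise ValueError("mixed k across samples")
        union = np.unique(np.concatenate([samples[c].codes for c in cols])) \
            if cols else np.zeros(0, np.uint64)
        mat = np.zeros((len(union), len(cols)), dtype=np.int64)
        for j, c in enumerate(cols):
            s = samples[c]
            idx = np.searchsorted(union, s.codes)
            mat[idx, j] = s.counts
        return cls(ks.pop(), union, mat, cols, all(s.canonical for s in samples.values()))

    def column_index(self, sex: str) -> list[int]:
        return [j for j, (_pop, s) in enumerate(self.columns) if s == sex]

    def take(self, mask: np.ndarray) -> "KmerCountMatrix":
        return KmerCountMatrix(self.k, self.codes[mask], self.counts[mask],
                               list(self.columns), self.canonical)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts,
                          columns=[f"{p}_{s}" for p, s in self.columns])
        df.insert(0, "kmer", [decode_kmer(int(c), self.k) for c in self.codes])
        return df


def female_filter(matrix: KmerCountMatrix,
                  max_female: int = 1, min_male: int = 1) -> KmerCountMatrix:
    """Keep rows with count <= max_female in every female column and
    >= min_male in every male column."""
    fidx = matrix.column_index("F")
    midx = matrix.column_index("M")
    if not fidx or not midx:
        raise ValueError("matrix needs at least one male and one female column")
    keep = (matrix.counts[:, fidx] <= max_female).all(axis=1)
    keep &= (matrix.counts[:, midx] >= min_male).all(axis=1)
    log.info("female_filter: %d/%d k-mers retained", int(keep.sum()), len(keep))
    return matrix.take(keep)


def male_cutoffs(filtered: KmerCountMatrix) -> pd.DataFrame:
    """Sample-specific male mean and 95% CI over the female-filtered matrix.

    The mean is the cutoff used for conserved y-mer calling; the CI is
    reported alongside, not enforced.
    """
    rows = []
    for j, (pop, sex) in enumerate(filtered.columns):
        if sex != "M":
            continue
        col = filtered.counts[:, j].astype(float)
        n = len(col)
        mean = col.mean() if n else float("nan")
        sd = col.std(ddof=1) if n > 1 else float("nan")
        half = 1.96 * sd / np.sqrt(n) if n > 1 else float("nan")
        rows.append((pop, mean, mean - half, mean + half, n))
    return pd.DataFrame(rows, columns=["population", "mean", "ci_low", "ci_high", "n_kmers"])


@dataclass
class YmerSet:
    """Conserved male-specific k-mers plus the cutoffs that defined them."""

    k: int
    codes: np.ndarray  # sorted uint64
    cutoffs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.codes)

    def contains(self, kmer: str) -> bool:
        code = np.uint64(canonical_code(encode_kmer(kmer), self.k))
        i = np.searchsorted(self.codes, code)
        return bool(i < len(self.codes) and self.codes[i] == code)


def call_conserved_ymers(matrix: KmerCountMatrix) -> YmerSet:
    """y-mers: count strictly above the sample-specific male mean in every
    male sample and 0 in every female sample, intersected across the whole
    panel. Input should be the female-filtered matrix."""
    if len(matrix.codes) == 0:
        return YmerSet(matrix.k, np.zeros(0, np.uint64), male_cutoffs(matrix))
    cut = male_cutoffs(matrix)
    keep = np.ones(len(matrix.codes), dtype=bool)
    means = dict(zip(cut["population"], cut["mean"]))
    for j, (pop, sex) in enumerate(matrix.columns):
        if sex == "M":
            keep &= matrix.counts[:, j] > means[pop]
        else:
            keep &= matrix.counts[:, j] == 0
    return YmerSet(matrix.k, matrix.codes[keep], cut)


def select_ymer_reads(r1, r2, ymers: YmerSet,
                      chunk_reads: int = 100_000) -> np.ndarray:
    """Boolean mask over read pairs: pair kept when either mate contains at
    least one y-mer on either strand."""
    if len(ymers) == 0:
        raise ValueError("empty y-mer set")
    m1, m2 = _as_matrix(r1), _as_matrix(r2)
    n = m1.shape[0]
    out = np.zeros(n, dtype=bool)
    for mat in (m1, m2):
        for lo in range(0, n, chunk_reads):
            codes = read_kmer_codes(mat[lo:lo + chunk_reads], ymers.k, canonical=True)
            idx = np.searchsorted(ymers.codes, codes)
            idx[idx == len(ymers.codes)] = len(ymers.codes) - 1
            hit = ymers.codes[idx] == codes
            out[lo:lo + chunk_reads] |= hit.any(axis=1)
    return out


# ---------------------------------------------------------------------------
# de Bruijn unitig assembly
# ---------------------------------------------------------------------------

def assemble_contigs(reads, assembly_k: int = 31, min_unitig_cov: int = 3,
                     min_len: int | None = None) -> list[str]:
    """Minimal de Bruijn unitig assembler.

    Builds the graph at ``assembly_k`` from both strands, drops k-mers seen
    fewer than ``min_unitig_cov`` times, and emits maximal unambiguous paths
    (unitigs) at least ``min_len`` bp (default 2 * assembly_k), deduplicated
    across strands and ordered by (length desc, sequence). Deterministic for
    fixed input and parameters. assembly_k is capped at 31 by the packed
    k-mer representation.
    """
    if min_len is None:
        min_len = 2 * assembly_k
    k = assembly_k
    counts = count_kmers(reads, k, canonical=True)
    solid = counts.codes[counts.counts >= min_unitig_cov]
    if len(solid) == 0:
        log.warning("assemble_contigs: no k-mer passes min_unitig_cov")
        return []
    # both orientations, directed
    fwd = [int(c) for c in solid]
    edges = set(fwd)
    for c in fwd:
        edges.add(_revcomp_int(c, k))
    nodes_out: dict[int, list[int]] = {}
    nodes_in: dict[int, list[int]] = {}
    nmask = (1 << (2 * (k - 1))) - 1
    for e in edges:
        pre = e >> 2
        suf = e & nmask
        nodes_out.setdefault(pre, []).append(e)
        nodes_in.setdefault(suf, []).append(e)

    def simple(node: int) -> bool:
        return len(nodes_out.get(node, [])) == 1 and len(nodes_in.get(node, [])) == 1

    visited: set[int] = set()
    unitigs: list[str] = []
    order = sorted(edges)
    for start in order:
        if start in visited:
            continue
        pre = start >> 2
        if simple(pre) and nodes_in[pre][0] not in visited:
            continue  # not a path start; will be reached by extension
        path = [start]
        visited.add(start)
        cur = start & nmask
        while simple(cur):
            nxt = nodes_out[cur][0]
            if nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt & nmask
        unitigs.append(_path_seq(path, k))
    # isolated cycles: everything left unvisited
    for start in order:
        if start in visited:
            continue
        path = [start]
        visited.add(start)
        cur = start & nmask
        while simple(cur):
            nxt = nodes_out[cur][0]
            if nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt & nmask
        unitigs.append(_path_seq(path, k))

    out = {}
    for seq in unitigs:
        if len(seq) < min_len:
            continue
        canon = min(seq, dna.revcomp_str(seq))
        out[canon] = True
    result = sorted(out, key=lambda s: (-len(s), s))
    if not result:
        log.warning("assemble_contigs: no unitig passes the length floor")
    return result


def _revcomp_int(code: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def _path_seq(path: list[int], k: int) -> str:
    first = decode_kmer(path[0], k)
    tail = "".join(dna.decode(np.array([p & 3], dtype=np.uint8)) for p in path[1:])
    return first + tail


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

@dataclass
class ReferenceIndex:
    """Exact seed k-mer index over a reference genome."""

    seed_k: int
    codes: np.ndarray      # sorted forward-strand codes
    starts: np.ndarray     # searchsorted boundaries into pos
    pos: np.ndarray        # global concatenated positions
    chrom_offsets: dict[str, tuple[int, int]]
    chrom_seqs: dict[str, np.ndarray]

    @classmethod
    def build(cls, reference: dict[str, np.ndarray | str],
              seed_k: int = 21) -> "ReferenceIndex":
        seqs = {c: (dna.encode(s) if isinstance(s, str) else np.asarray(s, dtype=np.uint8))
                for c, s in reference.items()}
        offsets = {}
        codes_parts, pos_parts = [], []
        off = 0
        for chrom in sorted(seqs):
            seq = seqs[chrom]
            offsets[chrom] = (off, off + len(seq))
            codes = read_kmer_codes(seq[None, :], seed_k, canonical=False)[0]
            valid = codes != _SENTINEL
            codes_parts.append(codes[valid])
            pos_parts.append(np.flatnonzero(valid) + off)
            off += len(seq)
        allc = np.concatenate(codes_parts)
        allp = np.concatenate(pos_parts)
        order = np.argsort(allc, kind="stable")
        allc, allp = allc[order], allp[order]
        edge = np.flatnonzero(np.diff(allc)) + 1
        starts = np.concatenate([[0], edge, [len(allc)]])
        uniq = allc[starts[:-1]]
        return cls(seed_k, uniq, starts, allp, offsets, seqs)

    def lookup(self, code: np.uint64) -> np.ndarray:
        i = np.searchsorted(self.codes, code)
        if i >= len(self.codes) or self.codes[i] != code:
            return np.zeros(0, dtype=np.int64)
        return self.pos[self.starts[i]:self.starts[i + 1]]

    def chrom_of(self, gpos: int) -> tuple[str, int]:
        for chrom, (lo, hi) in self.chrom_offsets.items():
            if lo <= gpos < hi:
                return chrom, gpos - lo
        raise ValueError(gpos)


def place_contigs(contigs: list[str], reference: dict[str, np.ndarray | str] | ReferenceIndex,
                  seed_k: int = 21, min_identity: float = 0.9,
                  min_cov_frac: float = 0.5) -> pd.DataFrame:
    """Seed-and-extend placement of contigs on a reference.

    Exact seed k-mers vote for (diagonal, position) candidates; the best
    candidate per strand is verified with an edlib infix alignment. The
    best-scoring location wins; ties break to the lowest (chrom, start);
    a contig is unplaced when no location reaches ``min_identity`` over at
    least ``min_cov_frac`` of its length.

    Returns a DataFrame: contig_index, length, chrom, start, end, strand,
    score (placed fraction identity); unplaced rows have chrom = NaN.
    """
    index = reference if isinstance(reference, ReferenceIndex) else \
        ReferenceIndex.build(reference, seed_k)
    rows = []
    for ci, contig in enumerate(contigs):
        best = None  # (-score, chrom, start, end, strand)
        for strand, seq in (("+", contig), ("-", dna.revcomp_str(contig))):
            cand = _candidate_positions(seq, index)
            for gstart in cand:
                chrom, cpos = index.chrom_of(int(gstart))
                ref = index.chrom_seqs[chrom]
                lo = max(0, cpos - 50)
                hi = min(len(ref), cpos + len(seq) + 50)
                window = dna.decode(ref[lo:hi])
                hit = _verify(seq, window, min_identity, min_cov_frac)
                if hit is None:
                    continue
                score, qfrac, wlo, whi = hit
                entry = (-score, chrom, lo + wlo, lo + whi, strand)
                if best is None or entry < best:
                    best = entry
        if best is None:
            rows.append((ci, len(contig), np.nan, -1, -1, ".", 0.0))
        else:
            negscore, chrom, start, end, strand = best
            rows.append((ci, len(contig), chrom, start, end, strand, -negscore))
    return pd.DataFrame(rows, columns=["contig_index", "length", "chrom",
                                       "start", "end", "strand", "score"])


def _candidate_positions(seq: str, index: ReferenceIndex,
                         max_candidates: int = 4) -> list[int]:
    """Most-voted seed diagonals -> approximate reference start positions."""
    codes = read_kmer_codes(dna.encode(seq)[None, :], index.seed_k, canonical=False)[0]
    diags: dict[int, int] = {}
    for qpos in range(0, len(codes), 4):  # stride seeds for speed
        code = codes[qpos]
        if code == _SENTINEL:
            continue
        for gpos in index.lookup(code):
            d = int(gpos) - qpos
            diags[d] = diags.get(d, 0) + 1
    if not diags:
        return []
    # merge nearby diagonals (small indels)
    items = sorted(diags.items(), key=lambda kv: (-kv[1], kv[0]))
    out: list[int] = []
    for d, _votes in items:
        if all(abs(d - o) > 30 for o in out):
            out.append(d)
        if len(out) >= max_candidates:
            break
    return out


def _verify(seq: str, window: str, min_identity: float,
            min_cov_frac: float):
    """edlib infix check; falls back to the better half for partial hits.

    Returns (score, covered_fraction, window_start, window_end) or None.
    """
    import edlib

    for frac, query, qoff in ((1.0, seq, 0),
                              (0.5, seq[: len(seq) // 2], 0),
                              (0.5, seq[len(seq) // 2:], len(seq) // 2)):
        if frac < 1.0 and len(seq) < 80:
            break
        if frac < min_cov_frac or not query:
            continue
        res = edlib.align(query, window, mode="HW", task="locations")
        if res["editDistance"] < 0:
            continue
        identity = 1 - res["editDistance"] / len(query)
        if identity >= min_identity:
            wlo, whi = res["locations"][0]
            return (identity * len(query), frac, wlo, whi + 1)
    return None


# ---------------------------------------------------------------------------
# recruitment
# ---------------------------------------------------------------------------

def recruitment_by_window(placements: pd.DataFrame, chrom_lengths: dict[str, int],
                          window_size: int = 100_000) -> pd.DataFrame:
    """Per-window per-population placed-contig counts (by placement
    midpoint) plus each chromosome's share of total placed length.

    ``placements`` must carry a 'population' column next to the
    place_contigs output columns.
    """
    placed = placements.dropna(subset=["chrom"]).copy()
    rows = []
    pops = sorted(placed["population"].unique()) if len(placed) else []
    for chrom, length in chrom_lengths.items():
        n_win = -(-length // window_size)
        for w in range(n_win):
            lo, hi = w * window_size, min((w + 1) * window_size, length)
            row = {"chrom": chrom, "start": lo, "end": hi}
            for pop in pops:
                sub = placed[(placed["population"] == pop) & (placed["chrom"] == chrom)]
                mid = (sub["start"] + sub["end"]) // 2
                row[pop] = int(((mid >= lo) & (mid < hi)).sum())
            rows.append(row)
    df = pd.DataFrame(rows)
    if len(placed):
        placed["placed_len"] = placed["end"] - placed["start"]
        share = placed.groupby("chrom")["placed_len"].sum()
        total = share.sum()
        df["chrom_length_share"] = df["chrom"].map(share / total).fillna(0.0)
    else:
        df["chrom_length_share"] = 0.0
    return df
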