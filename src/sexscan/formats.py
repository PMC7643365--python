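"""Containers and I/O for the standard formats the pipeline touches.

The in-memory substrates are:

* :class:`SampleTable` — who is who: sample id, sex (M/F), population.
* :class:`GenotypeMatrix` — biallelic SNP genotypes coded 0/1/2 (-1 missing),
  sites-by-samples, column order bound to the sample table.
* :class:`CoverageTrack` — per-individual binned depth, one matrix per
  chromosome, bins tiling the chromosome.

File formats: TSV sample sheet, VCF v4.2 (GT and optional DP), bedGraph,
BED6, FASTA/FASTQ (via Biopython). Parsers never silently drop records —
every rejection is counted and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

MISSING = -1  # genotype code for ./.


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

@dataclass
class SampleTable:
    """Sample id / sex / population assignments."""

    df: pd.DataFrame  # columns: id, sex, population

    def __post_init__(self) -> None:
        required = {"id", "sex", "population"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"sample sheet needs columns {sorted(required)}")
        if self.df["id"].duplicated().any():
            dup = self.df.loc[self.df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate sample id: {dup}")
        bad = set(self.df["sex"]) - {"M", "F"}
        if bad:
            raise ValueError(f"sex must be M or F, got {sorted(bad)}")
        self.df = self.df.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return self.df["id"].tolist()

    @property
    def populations(self) -> list[str]:
        return sorted(self.df["population"].unique())

    def members(self, population: str, sex: str) -> list[str]:
        m = (self.df["population"] == population) & (self.df["sex"] == sex)
        return self.df.loc[m, "id"].tolist()

    def sex_of(self, sample_id: str) -> str:
        row = self.df.loc[self.df["id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["sex"].iloc[0]

    def subset(self, ids: list[str]) -> "SampleTable":
        df = self.df.set_index("id").loc[ids].reset_index()
        return SampleTable(df)


def read_sample_sheet(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleTable(df)


def write_sample_sheet(table: SampleTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for a fixed sample panel.

    ``gt`` is (n_sites, n_samples) int8 with values 0/1/2 (alt allele dosage)
    or -1 for missing; ``depth`` is optional per-genotype read depth.
    ``sites`` has columns chrom, pos (0-based), ref, alt.
    """

    sites: pd.DataFrame
    gt: np.ndarray
    samples: list[str]
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.gt.shape != (len(self.sites), len(self.samples)):
            raise ValueError("gt shape does not match sites x samples")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def columns(self, ids: list[str]) -> np.ndarray:
        idx = [self.samples.index(i) for i in ids]
        return self.gt[:, idx]

    def depth_columns(self, ids: list[str]) -> np.ndarray | None:
        if self.depth is None:
            return None
        idx = [self.samples.index(i) for i in ids]
        return self.depth[:, idx]

    def take_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.sites.loc[mask].reset_index(drop=True),
            self.gt[mask],
            list(self.samples),
            None if self.depth is None else self.depth[mask],
        )


_GT_FROM_ALLELES = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}


def read_vcf(path, sample_table: SampleTable) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a GenotypeMatrix.

    Multiallelic and non-SNP records are dropped with a logged count.
    Samples present in the table but absent from the VCF raise an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    vcf_samples = list(vcf.samples)
    for s in sample_table.ids:
        if s not in vcf_samples:
            raise ValueError(f"sample {s!r} in sample sheet but not in VCF")
    order = np.array([vcf_samples.index(s) for s in sample_table.ids])

    rows, gts, depths = [], [], []
    n_dropped = 0
    has_depth = False
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_dropped += 1
            continue
        rows.append((var.CHROM, var.POS - 1, var.REF, var.ALT[0]))
        g = np.asarray(var.gt_types)[order].astype(np.int8)
        g[g == 3] = MISSING  # cyvcf2 gts012: 3 == unknown
        gts.append(g)
        try:
            dp = var.format("DP")
        except KeyError:  # DP absent from the header entirely
            dp = None
        if dp is not None:
            has_depth = True
            d = dp.reshape(-1)[order].astype(np.int32)
            d[d < 0] = 0
            depths.append(d)
        else:
            depths.append(np.zeros(len(order), dtype=np.int32))
    if n_dropped:
        log.info("read_vcf: dropped %d multiallelic/non-SNP records", n_dropped)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    gt = np.vstack(gts) if gts else np.zeros((0, len(order)), dtype=np.int8)
    depth = np.vstack(depths) if (depths and has_depth) else None
    return GenotypeMatrix(sites, gt, sample_table.ids, depth)


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as minimal VCF v4.2 with GT (and DP if held)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in matrix.sites["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if matrix.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.samples) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        fmt = "GT" if matrix.depth is None else "GT:DP"
        for i, row in enumerate(matrix.sites.itertuples(index=False)):
            fields = [row.chrom, str(row.pos + 1), ".", row.ref, row.alt, ".", "PASS", ".", fmt]
            if matrix.depth is None:
                cells = [gt_str[int(g)] for g in matrix.gt[i]]
            else:
                cells = [
                    f"{gt_str[int(g)]}:{int(d)}"
                    for g, d in zip(matrix.gt[i], matrix.depth[i])
                ]
            fh.write("\t".join(fields + cells) + "\n")


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Binned per-individual coverage; bins tile each chromosome.

    ``data[chrom]`` is (n_bins, n_samples) float64; NaN marks missing/filtered
    bins. ``chrom_lengths`` gives true lengths (last bin may be partial).
    """

    bin_size: int
    samples: list[str]
    chrom_lengths: dict[str, int]
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            n = -(-self.chrom_lengths[chrom] // self.bin_size)
            if arr.shape != (n, len(self.samples)):
                raise ValueError(f"{chrom}: expected {(n, len(self.samples))}, got {arr.shape}")

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            self.bin_size,
            list(self.samples),
            dict(self.chrom_lengths),
            {c: a.copy() for c, a in self.data.items()},
        )

    def bin_lengths(self, chrom: str) -> np.ndarray:
        """True genomic length of each bin (last bin may be short)."""
        n = self.data[chrom].shape[0]
        lens = np.full(n, self.bin_size, dtype=float)
        rem = self.chrom_lengths[chrom] - (n - 1) * self.bin_size
        lens[-1] = rem
        return lens

    def column(self, sample_id: str) -> dict[str, np.ndarray]:
        j = self.samples.index(sample_id)
        return {c: a[:, j] for c, a in self.data.items()}


def read_coverage_bedgraph(paths: dict[str, str], bin_size: int,
                           chrom_lengths: dict[str, int]) -> CoverageTrack:
    """Read one bedGraph per individual onto a common bin grid.

    Input intervals that misalign with the requested grid are re-binned by
    length-weighted mean. Malformed lines raise; empty files yield all-NaN.
    """
    samples = list(paths)
    data = {
        c: np.full((-(-length // bin_size), len(samples)), np.nan)
        for c, length in chrom_lengths.items()
    }
    weight = {c: np.zeros(a.shape) for c, a in data.items()}
    accum = {c: np.zeros(a.shape) for c, a in data.items()}
    for j, sample in enumerate(samples):
        with open(paths[sample]) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{paths[sample]}:{ln}: malformed bedGraph line")
                chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                if end <= start:
                    raise ValueError(f"{paths[sample]}:{ln}: empty interval")
                if chrom not in data:
                    continue
                b0, b1 = start // bin_size, -(-end // bin_size)
                for b in range(b0, b1):
                    lo = max(start, b * bin_size)
                    hi = min(end, (b + 1) * bin_size)
                    accum[chrom][b, j] += value * (hi - lo)
                    weight[chrom][b, j] += hi - lo
    for chrom in data:
        w = weight[chrom]
        with np.errstate(invalid="ignore"):
            data[chrom] = np.where(w > 0, accum[chrom] / np.where(w > 0, w, 1), np.nan)
    return CoverageTrack(bin_size, samples, dict(chrom_lengths), data)


def write_coverage_bedgraph(track: CoverageTrack, sample_id: str, path) -> None:
    col = track.column(sample_id)
    with open(path, "w") as fh:
        for chrom in sorted(col):
            vals = col[chrom]
            length = track.chrom_lengths[chrom]
            for b, v in enumerate(vals):
                if np.isnan(v):
                    continue
                start = b * track.bin_size
                end = min(start + track.bin_size, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# tables, BED
# ---------------------------------------------------------------------------

def write_windows_tsv(window_stats: pd.DataFrame, path) -> None:
    """Per-window statistics table, '.' for missing values."""
    window_stats.to_csv(path, sep="\t", index=False, na_rep=".")


def read_windows_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."])


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write BED (3 or 6 column) from a DataFrame with chrom/start/end
    and optional name/score/strand."""
    cols = ["chrom", "start", "end"]
    for extra in ("name", "score", "strand"):
        if extra in intervals.columns:
            cols.append(extra)
    intervals[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    """Return [(read_id, sequence)] from a FASTQ file (malformed -> error)."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
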