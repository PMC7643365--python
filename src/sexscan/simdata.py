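"""Synthetic multi-population XY cohorts with planted sex-linked architecture.

The generator builds a random reference genome, designates one chromosome as
the sex pair, and plants regions of five kinds:

* ``Y_SPECIFIC`` — sequence carried only by Y haplotypes (hemizygous in
  males, absent from females). The reference contains it, as a male-derived
  assembly would.
* ``Y_DIVERGED_MULTIHAP`` — an X–Y differentiated region where each male's Y
  carries one of several distinct low-frequency Y haplotypes. The haplotype
  classes are global (one ancestral Y lineage pool shared by all
  populations), assigned round-robin within each population so class
  frequencies are balanced.
* ``Y_SWEPT`` — a single Y haplotype fixed among all males (every male
  heterozygous, every female homozygous at its diagnostic sites).
* ``X_HEMIZYGOUS`` — region present on X only; males carry one copy.
* ``DUP_REPEAT`` — Y-derived repeat sequence that the reference assembly
  additionally carries at autosomal positions, producing coverage and
  contig-placement artifacts at those copies.

Neutral SNPs are planted at a configurable density with per-population
allele frequencies drawn around a shared ancestral frequency (between-
population heterogeneity without an explicit demographic model). All outputs
are deterministic functions of the config seed.

Coordinates are 0-based half-open throughout; 1-based only at VCF edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from . import dna
from .formats import CoverageTrack, GenotypeMatrix, SampleTable


class RegionKind(str, Enum):
    Y_SPECIFIC = "Y_SPECIFIC"
    Y_DIVERGED_MULTIHAP = "Y_DIVERGED_MULTIHAP"
    Y_SWEPT = "Y_SWEPT"
    X_HEMIZYGOUS = "X_HEMIZYGOUS"
    DUP_REPEAT = "DUP_REPEAT"


# truth signal classes the detection modules are expected to fire
SIGNALS = {
    RegionKind.Y_SPECIFIC: ["male_coverage_bias", "ymer_recruitment"],
    RegionKind.Y_DIVERGED_MULTIHAP: ["da_outlier"],
    RegionKind.Y_SWEPT: ["fst_outlier", "da_outlier"],
    RegionKind.X_HEMIZYGOUS: ["female_coverage_bias"],
    RegionKind.DUP_REPEAT: ["male_coverage_bias", "ymer_recruitment"],
}


@dataclass
class RegionSpec:
    """A planted region on the sex chromosome (0-based half-open)."""

    start: int
    end: int
    kind: RegionKind
    n_y_haplotypes: int = 1
    divergence: float = 0.02  # per-site X-Y difference probability per Y haplotype
    dup_targets: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.kind = RegionKind(self.kind)
        if self.end <= self.start:
            raise ValueError("region end must exceed start")
        if self.n_y_haplotypes < 1:
            raise ValueError("n_y_haplotypes must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimConfig:
    seed: int = 0
    n_populations: int = 6
    males_per_pop: int = 10
    females_per_pop: int = 10
    chrom_lengths: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 1_500_000), ("chr2", 1_500_000), ("chrXY", 2_000_000)]
    )
    sex_chrom: str = "chrXY"
    region_specs: list[RegionSpec] = field(default_factory=list)
    snp_density: float = 0.005  # expected segregating sites per bp
    read_len: int = 150
    depth: float = 10.0  # mean per-individual fold coverage
    base_error_rate: float = 0.001
    coverage_bin: int = 1000
    coverage_overdispersion: float = 0.05  # gamma noise, CV = sqrt(phi)

    def __post_init__(self) -> None:
        lengths = dict(self.chrom_lengths)
        if any(l <= 0 for l in lengths.values()):
            raise ValueError("all chromosome lengths must be > 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 <= self.base_error_rate < 0.5:
            raise ValueError("base_error_rate must be in [0, 0.5)")
        if self.coverage_overdispersion < 0:
            raise ValueError("coverage_overdispersion must be >= 0")
        if self.sex_chrom not in lengths:
            raise ValueError(f"sex_chrom {self.sex_chrom!r} not in chrom_lengths")
        sex_len = lengths[self.sex_chrom]
        regions = sorted(self.region_specs, key=lambda r: r.start)
        for r in regions:
            if not (0 <= r.start < r.end <= sex_len):
                raise ValueError(f"region {r.start}-{r.end} outside {self.sex_chrom}")
        for a, b in zip(regions, regions[1:]):
            if b.start < a.end:
                raise ValueError("region_specs overlap")
        for r in regions:
            for chrom, start in r.dup_targets:
                if chrom == self.sex_chrom:
                    raise ValueError("dup_targets must be autosomal")
                if chrom not in lengths or start + r.length > lengths[chrom]:
                    raise ValueError("dup target outside its chromosome")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chrom_lengths)

    @property
    def populations(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_populations)]


# ---------------------------------------------------------------------------
# system
# ---------------------------------------------------------------------------

@dataclass
class _NeutralSites:
    pos: np.ndarray           # (n_sites,), sorted
    alt_offset: np.ndarray    # (n_sites,) in {1,2,3}; alt base = (ref+off) % 4
    hap_alleles: np.ndarray   # (n_sites, n_samples, 2) uint8 in {0,1}


@dataclass
class _YDiagnostic:
    """X-Y differentiated sites of one region; class_idx says which Y
    haplotype class carries the alt allele."""

    pos: np.ndarray
    alt_offset: np.ndarray
    class_idx: np.ndarray


@dataclass
class SimSystem:
    config: SimConfig
    reference: dict[str, np.ndarray]
    sample_table: SampleTable
    neutral: dict[str, _NeutralSites]
    y_diag: list[_YDiagnostic]
    male_class: dict[str, int]  # sample id -> global Y haplotype class index
    truth: pd.DataFrame

    # ---- derived interval sets -------------------------------------------
    def _regions(self, *kinds: RegionKind) -> list[RegionSpec]:
        return [r for r in self.config.region_specs if r.kind in kinds]

    def x_absent_intervals(self) -> list[tuple[int, int]]:
        """Sex-chromosome intervals absent from X haplotypes."""
        return [(r.start, r.end) for r in self._regions(RegionKind.Y_SPECIFIC, RegionKind.DUP_REPEAT)]

    def y_absent_intervals(self) -> list[tuple[int, int]]:
        """Sex-chromosome intervals absent from Y haplotypes."""
        return [(r.start, r.end) for r in self._regions(RegionKind.X_HEMIZYGOUS)]

    def autosome_absent_intervals(self, chrom: str) -> list[tuple[int, int]]:
        """Dup-target intervals (reference-only repeat copies) on an autosome."""
        out = []
        for r in self._regions(RegionKind.DUP_REPEAT):
            for tchrom, tstart in r.dup_targets:
                if tchrom == chrom:
                    out.append((tstart, tstart + r.length))
        return out

    def hemizygous_intervals(self) -> list[tuple[str, int, int]]:
        """Intervals to drop from genotype output under the dropout flag."""
        out = [
            (self.config.sex_chrom, r.start, r.end)
            for r in self._regions(RegionKind.Y_SPECIFIC, RegionKind.DUP_REPEAT)
        ]
        for r in self._regions(RegionKind.DUP_REPEAT):
            for tchrom, tstart in r.dup_targets:
                out.append((tchrom, tstart, tstart + r.length))
        return out

    # ---- haplotype construction ------------------------------------------
    def haplotypes(self, sample_id: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Materialize the two haplotype sequences of one individual.

        Returns {chrom: (hap1, hap2)}; for males hap2 of the sex chromosome
        is the Y. Deleted intervals are excised, so haplotype lengths differ
        between sexes on the sex chromosome.
        """
        cfg = self.config
        j = self.sample_table.ids.index(sample_id)
        sex = self.sample_table.sex_of(sample_id)
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, _length in cfg.chrom_lengths:
            ref = self.reference[chrom]
            sites = self.neutral[chrom]
            haps = []
            for h in (0, 1):
                seq = ref.copy()
                alleles = sites.hap_alleles[:, j, h]
                alt = (ref[sites.pos] + sites.alt_offset) % 4
                seq[sites.pos[alleles == 1]] = alt[alleles == 1].astype(np.uint8)
                haps.append(seq)
            if chrom == cfg.sex_chrom:
                if sex == "M":
                    y = haps[1]
                    cls = self.male_class[sample_id]
                    for diag in self.y_diag:
                        mine = (diag.class_idx == cls) | (diag.class_idx == -1)
                        alt = (ref[diag.pos[mine]] + diag.alt_offset[mine]) % 4
                        y[diag.pos[mine]] = alt.astype(np.uint8)
                    # Y never carries neutral X variation inside diverged regions
                    # (enforced at draw time), nothing to undo here.
                    haps = [
                        _excise(haps[0], self.x_absent_intervals()),
                        _excise(y, self.y_absent_intervals()),
                    ]
                else:
                    haps = [_excise(h, self.x_absent_intervals()) for h in haps]
            else:
                absent = self.autosome_absent_intervals(chrom)
                if absent:
                    haps = [_excise(h, absent) for h in haps]
            out[chrom] = (haps[0], haps[1])
        return out


def _excise(seq: np.ndarray, intervals: list[tuple[int, int]]) -> np.ndarray:
    if not intervals:
        return seq
    keep = np.ones(len(seq), dtype=bool)
    for s, e in intervals:
        keep[s:e] = False
    return seq[keep]


def _interval_mask(n: int, intervals: list[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


# ---------------------------------------------------------------------------
# simulate_system
# ---------------------------------------------------------------------------

def simulate_system(config: SimConfig) -> SimSystem:
    """Build reference, cohort, per-individual variation, and truth table."""
    lengths = config.lengths
    ss = np.random.SeedSequence(config.seed)
    rng_ref, rng_neutral, rng_diag, rng_assign = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    # reference
    reference = {c: dna.random_seq(rng_ref, l) for c, l in config.chrom_lengths}
    # stamp dup-target copies of the Y-derived source sequence into the reference
    for r in config.region_specs:
        if r.kind is RegionKind.DUP_REPEAT:
            src = reference[config.sex_chrom][r.start:r.end]
            for tchrom, tstart in r.dup_targets:
                reference[tchrom][tstart:tstart + r.length] = src

    # cohort
    rows = []
    for p, pop in enumerate(config.populations):
        for i in range(config.males_per_pop):
            rows.append((f"{pop}_M{i + 1}", "M", pop))
        for i in range(config.females_per_pop):
            rows.append((f"{pop}_F{i + 1}", "F", pop))
    table = SampleTable(pd.DataFrame(rows, columns=["id", "sex", "population"]))
    n_samples = len(table.ids)
    pop_of = np.array([config.populations.index(p) for p in table.df["population"]])
    is_male = (table.df["sex"] == "M").to_numpy()

    # Y haplotype classes: global pool, balanced round-robin within each population
    classes = [r.n_y_haplotypes for r in config.region_specs
               if r.kind is RegionKind.Y_DIVERGED_MULTIHAP]
    n_classes = max(classes) if classes else 1
    male_class: dict[str, int] = {}
    for pop in config.populations:
        males = table.members(pop, "M")
        order = rng_assign.permutation(len(males))
        for slot, m in enumerate(order):
            male_class[males[m]] = slot % n_classes

    # X-Y diagnostic sites for diverged/swept regions
    sex_len = lengths[config.sex_chrom]
    barred = _interval_mask(sex_len, [
        (r.start, r.end) for r in config.region_specs
        if r.kind in (RegionKind.Y_SPECIFIC, RegionKind.DUP_REPEAT)
    ])
    y_diag: list[_YDiagnostic] = []
    taken = np.zeros(sex_len, dtype=bool)
    for r in config.region_specs:
        if r.kind not in (RegionKind.Y_DIVERGED_MULTIHAP, RegionKind.Y_SWEPT):
            continue
        if r.kind is RegionKind.Y_DIVERGED_MULTIHAP:
            cls_ids = list(range(r.n_y_haplotypes))
        else:  # swept: one haplotype carried by every Y, class -1
            cls_ids = [-1]
        pos_list, cls_list = [], []
        for c in cls_ids:
            hit = rng_diag.random(r.length) < r.divergence
            pos = np.flatnonzero(hit) + r.start
            pos = pos[~taken[pos]]
            taken[pos] = True
            pos_list.append(pos)
            cls_list.append(np.full(len(pos), c))
        pos = np.concatenate(pos_list)
        cls = np.concatenate(cls_list)
        order = np.argsort(pos)
        y_diag.append(_YDiagnostic(
            pos=pos[order],
            alt_offset=rng_diag.integers(1, 4, size=len(pos))[order].astype(np.uint8),
            class_idx=cls[order].astype(np.int32),
        ))

    # neutral segregating sites
    diverged = _interval_mask(sex_len, [
        (r.start, r.end) for r in config.region_specs
        if r.kind in (RegionKind.Y_DIVERGED_MULTIHAP, RegionKind.Y_SWEPT)
    ])
    neutral: dict[str, _NeutralSites] = {}
    for chrom, length in config.chrom_lengths:
        hit = rng_neutral.random(length) < config.snp_density
        pos = np.flatnonzero(hit)
        if chrom == config.sex_chrom:
            pos = pos[~barred[pos] & ~taken[pos]]
        else:
            absent = _interval_mask(length, [])
            for r in config.region_specs:
                if r.kind is RegionKind.DUP_REPEAT:
                    for tchrom, tstart in r.dup_targets:
                        if tchrom == chrom:
                            absent[tstart:tstart + r.length] = True
            pos = pos[~absent[pos]]
        n_sites = len(pos)
        # shared ancestral frequency, mild independent per-population drift
        p0 = rng_neutral.uniform(0.1, 0.9, size=n_sites)
        conc = 50.0
        pop_freq = rng_neutral.beta(
            p0[:, None] * conc, (1 - p0[:, None]) * conc,
            size=(n_sites, config.n_populations),
        )
        p_ind = pop_freq[:, pop_of]  # (n_sites, n_samples)
        draws = rng_neutral.random((n_sites, n_samples, 2))
        alleles = (draws < p_ind[:, :, None]).astype(np.uint8)
        if chrom == config.sex_chrom and n_sites:
            # male hap2 is the Y: fixed reference inside diverged/swept regions
            in_div = diverged[pos]
            alleles[np.ix_(in_div, is_male)] &= np.array([1, 0], dtype=np.uint8)
        neutral[chrom] = _NeutralSites(
            pos=pos,
            alt_offset=rng_neutral.integers(1, 4, size=n_sites).astype(np.uint8),
            hap_alleles=alleles,
        )

    # truth table
    truth_rows = []
    for r in config.region_specs:
        for sig in SIGNALS[r.kind]:
            if r.kind is RegionKind.DUP_REPEAT:
                continue
            truth_rows.append((config.sex_chrom, r.start, r.end, r.kind.value, sig))
        if r.kind is RegionKind.DUP_REPEAT:
            truth_rows.append((config.sex_chrom, r.start, r.end,
                               r.kind.value, "male_coverage_bias"))
            for tchrom, tstart in r.dup_targets:
                for sig in ("coverage_artifact", "ymer_recruitment"):
                    truth_rows.append((tchrom, tstart, tstart + r.length,
                                       r.kind.value, sig))
    truth = pd.DataFrame(truth_rows, columns=["chrom", "start", "end", "kind", "signal"])

    return SimSystem(config, reference, table, neutral, y_diag, male_class, truth)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass
class ReadPairs:
    """Paired reads as code matrices; mate 2 is the reverse-complemented
    far end of the fragment."""

    r1: np.ndarray  # (n, read_len) uint8
    r2: np.ndarray
    sample_id: str

    @property
    def n_pairs(self) -> int:
        return self.r1.shape[0]


def simulate_reads(system: SimSystem, sample_id: str,
                   fragment_gap: int = 50) -> ReadPairs:
    """Draw error-bearing read pairs uniformly from one individual's
    haplotypes at the configured depth.

    Deterministic per (seed, individual): regenerating an individual's reads
    yields identical output, which lets downstream passes stream reads
    without caching them.
    """
    cfg = system.config
    idx = system.sample_table.ids.index(sample_id)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919, idx]))
    frag_len = 2 * cfg.read_len + fragment_gap
    haps = system.haplotypes(sample_id)
    pieces = []
    for chrom in haps:
        for h in (0, 1):
            seq = haps[chrom][h]
            if len(seq) == 0:
                continue
            if frag_len > len(seq):
                raise ValueError(
                    f"read/fragment length {frag_len} exceeds {chrom} haplotype "
                    f"length {len(seq)}"
                )
            pieces.append(seq)
    r1_parts, r2_parts = [], []
    for seq in pieces:
        n_pairs = int(round(cfg.depth / 2 * len(seq) / (2 * cfg.read_len)))
        if n_pairs == 0:
            continue
        starts = rng.integers(0, len(seq) - frag_len + 1, size=n_pairs)
        frag_idx = starts[:, None] + np.arange(frag_len)
        frags = seq[frag_idx]
        r1_parts.append(frags[:, :cfg.read_len].copy())
        # mate 2: reverse complement of the fragment's far end
        r2_parts.append((3 - frags[:, -cfg.read_len:][:, ::-1]).astype(np.uint8))
        del frags
    r1 = np.vstack(r1_parts)
    r2 = np.vstack(r2_parts)
    if cfg.base_error_rate > 0:
        for mat in (r1, r2):
            hits = rng.random(mat.shape, dtype=np.float32) < cfg.base_error_rate
            n_err = int(hits.sum())
            if n_err:
                mat[hits] = (mat[hits] + rng.integers(1, 4, size=n_err)) % 4
    return ReadPairs(r1, r2, sample_id)


def write_reads_fastq(reads: ReadPairs, path_r1, path_r2) -> None:
    for path, mat, mate in ((path_r1, reads.r1, 1), (path_r2, reads.r2, 2)):
        with open(path, "w") as fh:
            qual = "I" * mat.shape[1]
            for i in range(mat.shape[0]):
                fh.write(f"@{reads.sample_id}_{i}/{mate}\n{dna.decode(mat[i])}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def genotypes_from_system(system: SimSystem,
                          dropout_in_hemizygous: bool = True) -> GenotypeMatrix:
    """Perfect diploid genotypes at all polymorphic sites.

    Male genotypes inside X-hemizygous regions are emitted as the doubled
    single X allele (what a naive diploid caller reports). With the dropout
    flag, sites inside Y-specific and duplicated-repeat intervals are
    omitted, mirroring the SNP deserts such regions show after filtering.
    """
    cfg = system.config
    table = system.sample_table
    n_samples = len(table.ids)
    is_male = (table.df["sex"] == "M").to_numpy()
    male_cls = np.array([system.male_class.get(s, -1) for s in table.ids])

    xhem = _interval_mask(cfg.lengths[cfg.sex_chrom], system.y_absent_intervals())

    all_sites, all_gt = [], []
    for chrom, _length in cfg.chrom_lengths:
        ref = system.reference[chrom]
        sites = system.neutral[chrom]
        pos = sites.pos
        gt = sites.hap_alleles.sum(axis=2).astype(np.int8)
        alt_off = sites.alt_offset
        if chrom == cfg.sex_chrom:
            if len(pos):
                in_xhem = xhem[pos]
                # males carry only hap1 there; report the doubled allele
                h1 = sites.hap_alleles[:, :, 0]
                sel = np.ix_(in_xhem, is_male)
                gt[sel] = (2 * h1[sel]).astype(np.int8)
            diag_pos = [d.pos for d in system.y_diag]
            if diag_pos:
                dpos = np.concatenate(diag_pos)
                dalt = np.concatenate([d.alt_offset for d in system.y_diag])
                dcls = np.concatenate([d.class_idx for d in system.y_diag])
                # male het iff his Y class carries the variant (-1 = every Y)
                dgt = ((dcls[:, None] == male_cls[None, :])
                       | (dcls[:, None] == -1)).astype(np.int8)
                dgt[:, ~is_male] = 0
                pos = np.concatenate([pos, dpos])
                gt = np.vstack([gt, dgt])
                alt_off = np.concatenate([alt_off, dalt])
            order = np.argsort(pos)
            pos, gt, alt_off = pos[order], gt[order], alt_off[order]
        if dropout_in_hemizygous:
            drop = _interval_mask(len(ref), [
                (s, e) for (c, s, e) in system.hemizygous_intervals() if c == chrom
            ])
            keep = ~drop[pos] if len(pos) else np.ones(0, dtype=bool)
            pos, gt, alt_off = pos[keep], gt[keep], alt_off[keep]
        # polymorphic only
        tot = gt.sum(axis=1)
        poly = (tot > 0) & (tot < 2 * n_samples)
        pos, gt, alt_off = pos[poly], gt[poly], alt_off[poly]
        refb = ref[pos]
        altb = (refb + alt_off) % 4
        all_sites.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos,
            "ref": [dna.decode(np.array([b])) for b in refb],
            "alt": [dna.decode(np.array([b])) for b in altb],
        }))
        all_gt.append(gt)
    sites = pd.concat(all_sites, ignore_index=True)
    gt = np.vstack(all_gt) if all_gt else np.zeros((0, n_samples), dtype=np.int8)
    depth = np.full(gt.shape, int(round(cfg.depth)), dtype=np.int32)
    return GenotypeMatrix(sites, gt, table.ids, depth)


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def coverage_from_system(system: SimSystem) -> CoverageTrack:
    """Analytic binned coverage from the copy-number model (no read mapping).

    Bin depth is Gamma(1/phi, mean*phi) around mean = depth * copies / 2,
    degenerating to the exact mean at phi = 0. Copy weights: autosomes 2;
    Y-specific and duplicated-repeat intervals 2 in males (the full
    diploid-equivalent read share concentrates on the one locus) and 0 in
    females; X-hemizygous intervals 1 in males, 2 in females.
    """
    cfg = system.config
    table = system.sample_table
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 104729]))
    is_male = (table.df["sex"] == "M").to_numpy()
    phi = cfg.coverage_overdispersion
    bin_size = cfg.coverage_bin

    def copy_profile(chrom: str, length: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-bin copy weight for (male, female)."""
        n_bins = -(-length // bin_size)
        male = np.full(n_bins, 2.0)
        female = np.full(n_bins, 2.0)

        def paint(start: int, end: int, cm: float, cf: float) -> None:
            for b in range(start // bin_size, -(-end // bin_size)):
                lo, hi = max(start, b * bin_size), min(end, (b + 1) * bin_size)
                blen = min((b + 1) * bin_size, length) - b * bin_size
                f = (hi - lo) / blen
                male[b] = male[b] * (1 - f) + cm * f
                female[b] = female[b] * (1 - f) + cf * f

        for r in cfg.region_specs:
            if chrom == cfg.sex_chrom:
                if r.kind in (RegionKind.Y_SPECIFIC, RegionKind.DUP_REPEAT):
                    paint(r.start, r.end, 2.0, 0.0)
                elif r.kind is RegionKind.X_HEMIZYGOUS:
                    paint(r.start, r.end, 1.0, 2.0)
            if r.kind is RegionKind.DUP_REPEAT:
                for tchrom, tstart in r.dup_targets:
                    if tchrom == chrom:
                        paint(tstart, tstart + r.length, 2.0, 0.0)
        return male, female

    data = {}
    for chrom, length in cfg.chrom_lengths:
        male_c, female_c = copy_profile(chrom, length)
        n_bins = len(male_c)
        mean = np.where(is_male[None, :], male_c[:, None], female_c[:, None]) * cfg.depth / 2
        if phi == 0:
            vals = mean
        else:
            vals = rng.gamma(1.0 / phi, phi * mean)
        data[chrom] = vals
    return CoverageTrack(bin_size, table.ids, cfg.lengths, data)


def write_truth_bed(system: SimSystem, path) -> None:
    df = system.truth.copy()
    df["name"] = df["kind"] + ":" + df["signal"]
    df["score"] = 0
    df["strand"] = "."
    from .formats import write_bed

    write_bed(df, path)
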