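# Methods

`sexscan` detects sex-linked genomic regions in species with homomorphic or
weakly differentiated sex chromosomes, where the Y (or W) cannot be
assembled or even reliably mapped. It combines three detection tracks that
respond to different sex-linked architectures, intersects them across
populations, and ships a synthetic-cohort generator that plants each
architecture so the whole pipeline is verifiable end to end.

## Detection model

**Coverage track.** A region present only on the Y shows male reads and no
female reads; a region lost from the Y (X-hemizygous) shows males at half
the female depth. Per-individual binned depth is smoothed with a centered
moving average (width `smooth_len`, floored to an odd number of whole
bins), scaled RPGC-style so each individual's genome-wide mean over
untrimmed bins is 1, end-trimmed (`trim_bp`, default 100 kb per chromosome
end, where assembly artifacts concentrate), and masked where normalized
coverage exceeds `max_norm_cov` (default 4 — collapsed repeats). Windows
(default 10 kb) take length-weighted means over surviving bins; the
per-population statistic is log2 of (mean over male individuals)/(mean
over female individuals), classified male-biased above +0.75 and
female-biased below −0.75 — cutoffs sitting between the expected ratio
peaks at 0 (autosomal), +1 (Y-specific under the scan's conventions) and
−1 (X-hemizygous). A window with zero female mean but positive male mean
is assigned +infinity and classified male-biased deliberately: that is
precisely the Y-specific signature, and a pseudocount would shrink the
headline signal.

**SNP track.** Within each population the sexes are treated as two
"populations" of a two-deme model. Per 10-kb window we report, with window
length in bp as denominator so values are per-site and comparable across
windows with different SNP counts:

- π within each sex (unbiased pairwise diversity, `2j(n−j)/(n(n−1))`);
- D_XY between the sexes (`p_m(1−p_f) + p_f(1−p_m)` summed over sites);
- **net divergence D_a = D_XY − π_female** — the workhorse statistic: an
  abundance of low-frequency male-specific variants (many distinct
  segregating Y haplotypes) raises male diversity and D_XY without raising
  female π, lighting up D_a while leaving F_ST low;
- between-sex F_ST as Nei/Chesser (1983) sample-size-corrected G_ST,
  ratio-of-sums over window sites. On the canonical fully sex-linked
  configuration (all males heterozygous, all females homozygous) this
  estimator returns exactly 1/3, the textbook expectation for an XY site.
  The Hudson–Bhatia estimator (≈0.5 on the same configuration) is exposed
  as `estimator="hudson"` for comparison. Negative estimates are retained
  so the null distribution stays intact;
- F_IS per sex (1 − ΣH_obs/ΣH_exp); a strong male heterozygote excess
  (negative F_IS) is the sex-linkage direction.

Sites first pass the filter chain: per-genotype depth in [5, 200],
missingness ≤ 10% per population, minor allele frequency ≥ 5% per
population (inclusive at the boundary, as in vcftools), and — by default —
retention in every population. Outlier windows are those beyond the
population's genome-wide mean ± 3 SD (high tail for D_a/F_ST, low tail for
male F_IS). Windows left without usable SNPs are reported missing, never
zero: hemizygous and repeat-dense regions produce exactly such SNP deserts
and a zero would masquerade as evidence of no differentiation.

**y-mer track.** Sequence absent from the female genome never aligns to
anything informative, so it is sought alignment-free. Canonical 31-mers
(min of k-mer and reverse complement; k configurable) are counted per
pooled sex-within-population sample (default pools: 5 males, 5 females). A
female-filtered matrix keeps k-mers with count ≤ 1 in every female column
(tolerating one stray error hit) and ≥ 1 in every male column. Conserved
y-mers must additionally exceed the sample-specific male mean count
(computed over the female-filtered matrix; the 95% CI of that mean is
reported but not enforced) in every male sample and be exactly absent
(count 0) from every female sample. Reads whose either mate carries a
y-mer on either strand are selected and assembled with a minimal de Bruijn
unitig assembler (graph at `assembly_k` ≤ 31 from both strands, k-mers
below `min_unitig_cov` = 3 dropped, maximal unambiguous paths ≥
2·`assembly_k` bp emitted, deduplicated across strands, deterministic
ordering). Contigs are placed on the reference by exact-seed voting
(21-mers, strided) followed by edlib infix verification; a placement needs
≥ 90% identity over ≥ 50% of the contig, ties break to the lowest
(chromosome, coordinate) — which is what routes contigs from Y-derived
repeats to their lowest-coordinate autosomal copies, reproducing the
recruitment artifacts such repeats cause in real scans.

**Candidate caller.** Windows are flagged per population per evidence
type; support is the number of flagging populations. Tier 1 = (male-biased
coverage in all populations AND contig recruitment in all populations) OR
(D_a outlier in all populations). Tier 2 = any single evidence type
consistent across populations. F_ST > 0.3 windows are carried as
supplementary evidence only, because multiple segregating Y haplotypes
make between-sex F_ST inconsistent across populations. Adjacent qualifying
windows merge, bridging one missing window, since real signals arrive as
window clusters broken by filtered gaps.

## Synthetic cohorts

The generator emulates a multi-population resequencing study: by default 6
populations × (10 males + 10 females) at 10× per individual over a compact
5-Mb genome (two 1.5-Mb autosomes, one 2-Mb XY pair). Females carry two X
haplotypes, males an X and a Y. Planted architectures:

- `Y_SPECIFIC` (default 20 kb): reference sequence carried only by Y
  haplotypes — hemizygous in males, absent in females — as in a
  male-derived assembly;
- `Y_DIVERGED_MULTIHAP` (40 kb, 5 haplotypes, 2% divergence per
  haplotype): each Y carries one of several global variant sets, assigned
  round-robin within populations. The classes are shared across
  populations (one ancestral Y lineage pool); population-private Y
  variants would fail the per-population MAF filter and could not produce
  a cross-population D_a signal;
- `Y_SWEPT` (optional, 40 kb, 10% divergence): one variant set on every Y —
  every male heterozygous, every female homozygous. The higher default
  divergence makes the diagnostic sites dominate window heterozygosity, as
  they must for a swept stratum to show the > 0.3 window F_ST that defines
  this architecture; at 2% divergence the neutral X-linked diversity in
  the window dilutes the ratio-of-sums below 0.3;
- `X_HEMIZYGOUS` (40 kb): present on X only; males at half female depth;
- `DUP_REPEAT` (10 kb): Y-derived repeat whose copies the reference also
  carries at autosomal positions; produces male-biased coverage and
  contig-recruitment artifacts at the copies.

Neutral SNPs arrive at `snp_density` (default 0.005/bp) with ancestral
frequencies uniform on [0.1, 0.9] and per-population frequencies drawn
Beta-distributed around them (concentration 50) — between-population
heterogeneity without an explicit demographic model. Resulting π ≈ 0.002/bp.
Reads are error-bearing 150-bp pairs drawn uniformly from each
individual's haplotypes; binned coverage is generated directly from the
copy-number model as Gamma(1/φ, μφ) with mean μ = depth × copies/2 and
overdispersion φ (default 0.05, CV ≈ 22%), degenerating to the exact mean
at φ = 0. Every output is a deterministic function of the seed;
per-individual read streams regenerate independently, so multi-pass
k-mer scans never cache reads.

What the generator does **not** emulate: mapping (coverage bypasses
alignment, so mappability, GC bias, and paralog mis-mapping are only
represented through the explicit copy-number and duplication devices);
recombination structure and linkage disequilibrium beyond complete
X–Y linkage in the planted regions; indels and structural variation other
than the planted insertions/deletions; base-quality structure. Passing
tests therefore demonstrate that the statistics, filters, and intersection
logic behave as designed on data satisfying their assumptions — not that
the thresholds are robust to mapping artifacts in any particular real
dataset.

## Numerical and design choices

- Coordinates are 0-based half-open internally; 1-based only at VCF edges.
- Classification cutoffs are strict inequalities (a bin at exactly 4.0
  survives the coverage filter; a window at exactly 0.75 is unbiased).
- The coverage >4 mask is applied after smoothing and before windowing.
- Missing genotypes are excluded from allele counts site-wise, never
  imputed.
- k-mers are packed 2 bits/base into uint64 (k ≤ 31); canonical choice on
  packed codes coincides with lexicographic order. Counting is exact:
  chunked vectorized extraction, one sort, run-length counts. At pipeline
  scale the per-sample counts stream against a shrinking candidate set
  (full count of the first male pool only); the surviving row set and the
  male-mean cutoffs are identical to materializing the full master matrix.
- The assembler prunes by k-mer count before graph construction;
  `min_unitig_cov` = 3 stands in for the error correction a read-cleaning
  preprocessor would provide (the default simulated error rate is 0.1%).
- Placement ties (identical repeat copies) break deterministically to the
  lowest coordinate rather than randomly or to "unplaced", making the
  artifact they cause reproducible and testable.
- Degenerate inputs: an all-zero coverage track, an empty y-mer set, and
  overlapping region specs raise errors; chromosomes shorter than twice
  the trim are dropped with a warning; empty windows/columns propagate as
  missing.

## Problem sizes

The default study system (5-Mb genome, 120 individuals, 10×, 5+5 k-mer
pools) runs end to end in a few minutes on one core, the y-mer stage
dominating (~3 Gbp of reads streamed twice). The acceptance checkpoints
use analytic configurations (50 SNPs; 200 Mb of binned coverage for the
ratio benchmarks) and run in seconds. These sizes were chosen so the full
evidence chain — simulation through candidate calling — is exercised at
every test run while the planted signals remain far above their detection
thresholds (e.g., the diverged region's window D_a of ~0.01/bp against a
null SD of ~3×10⁻⁴).

## Limitations

- Between-sex F_ST expectations depend on the estimator; values quoted
  here (1/3 full-linkage) are specific to the corrected Nei/Chesser G_ST.
  The identical-groups value is 0 only in expectation: O(1/n) correction
  terms leave small nonzero samples (the 2+2-individual worked example in
  the tests evaluates to −0.2).
- The conserved-y-mer cutoff ("above the sample-specific male mean") is
  aggressive when the female-filtered matrix contains mostly true signal,
  as in clean simulations: requiring above-mean counts in all samples
  independently thins the set to the upper tail (~1–2% of male-specific
  k-mers here). That is faithful to the rule and still yields hundreds of
  y-mers and full contig recovery; on noisy real matrices the mean sits in
  the error floor and the cutoff behaves as a noise gate.
- The placement verifier reports one best location; split alignments
  across structural breakpoints are reported by their better half.
- With a single population, "consistent across populations" degenerates to
  single-population evidence; the caller does not correct for the reduced
  specificity.
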