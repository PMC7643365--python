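"""y-mer machinery: canonical counting vs a dictionary oracle, the female
filter and conserved-y-mer rules, read selection, unitig assembly, and
seed-and-extend placement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sexscan import dna, ymer
from sexscan.ymer import KmerCountMatrix, KmerCounts, YmerSet


def naive_kmer_counts(reads: list[str], k: int) -> dict[str, int]:
    """Brute-force canonical k-mer dictionary."""
    out: dict[str, int] = {}
    for read in reads:
        for i in range(len(read) - k + 1):
            kmer = read[i:i + k]
            if set(kmer) - set("ACGT"):
                continue
            canon = min(kmer, dna.revcomp_str(kmer))
            out[canon] = out.get(canon, 0) + 1
    return out


dna_alphabet = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestCounting:
    def test_poly_t_collapses_to_canonical_aaa(self):
        counts = ymer.count_kmers(["TTTT"], k=3)
        assert counts.to_dict() == {"AAA": 2}

    def test_palindrome_counts_as_itself(self):
        counts = ymer.count_kmers(["ACGTA"], k=4)
        assert counts.to_dict() == {"ACGT": 1, "CGTA": 1}

    def test_n_containing_kmers_skipped(self):
        counts = ymer.count_kmers(["ACNGT"], k=2)
        # CN and NG are skipped; GT canonicalizes to AC
        assert counts.to_dict() == {"AC": 2}

    def test_k_longer_than_reads_warns_and_is_empty(self, caplog):
        with caplog.at_level("WARNING"):
            counts = ymer.count_kmers(["ACGT"], k=9)
        assert counts.n_kmers == 0
        assert "exceeds" in caplog.text

    def test_matches_naive_oracle_on_random_reads(self):
        rng = np.random.default_rng(5)
        reads = ["".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04],
                                    size=rng.integers(20, 60)))
                 for _ in range(1000)]
        for k in (5, 13):
            got = ymer.count_kmers(reads, k).to_dict()
            assert got == naive_kmer_counts(reads, k)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(dna_alphabet, min_size=1, max_size=8), st.integers(2, 9))
    def test_canonical_symmetry(self, reads, k):
        """A read set and its reverse-complemented copy count identically."""
        fwd = ymer.count_kmers(reads, k)
        rev = ymer.count_kmers([dna.revcomp_str(r) for r in reads], k)
        assert fwd.to_dict() == rev.to_dict()

    def test_count_in_set_matches_full_count(self):
        rng = np.random.default_rng(9)
        reads = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(200)]
        full = ymer.count_kmers(reads, 11)
        sub = full.codes[::3]
        got = ymer.count_in_set(reads, 11, sub)
        assert np.array_equal(got, full.counts[::3])


def matrix_from_counts(k, rows: dict[str, dict]) -> KmerCountMatrix:
    """rows: kmer -> {(pop, sex): count}"""
    cols = sorted({c for v in rows.values() for c in v})
    codes = np.array(sorted(
        ymer.canonical_code(ymer.encode_kmer(s), k) for s in rows), dtype=np.uint64)
    by_code = {np.uint64(ymer.canonical_code(ymer.encode_kmer(s), k)): v
               for s, v in rows.items()}
    counts = np.array([[by_code[c].get(col, 0) for col in cols] for c in codes],
                      dtype=np.int64)
    return KmerCountMatrix(k, codes, counts, cols)


class TestFemaleFilterAndConserved:
    def test_female_filter_rules(self):
        m = matrix_from_counts(5, {
            "AAACC": {("p1", "F"): 0, ("p2", "F"): 1, ("p1", "M"): 3, ("p2", "M"): 5},
            "AAAGG": {("p1", "F"): 2, ("p2", "F"): 0, ("p1", "M"): 3, ("p2", "M"): 5},
            "AAATT": {("p1", "F"): 0, ("p2", "F"): 0, ("p1", "M"): 0, ("p2", "M"): 5},
        })
        out = ymer.female_filter(m)
        assert len(out.codes) == 1
        assert ymer.decode_kmer(int(out.codes[0]), 5) == "AAACC"

    def test_matrix_outer_join_from_columns(self):
        a = ymer.count_kmers(["AAAAA"], 5)
        b = ymer.count_kmers(["CCCCCC"], 5)
        m = KmerCountMatrix.from_columns({("p1", "M"): a, ("p1", "F"): b})
        assert m.counts.shape == (2, 2)
        frame = m.to_frame()
        assert set(frame["kmer"]) == {"AAAAA", "CCCCC"}  # canonical of GGGGG

    def test_conserved_rules(self):
        """Member: above male mean everywhere, zero in all females; a count
        of 1 in a single female excludes; sub-mean male count excludes."""
        m = matrix_from_counts(5, {
            "AAACC": {("p1", "F"): 0, ("p2", "F"): 0, ("p1", "M"): 30, ("p2", "M"): 30},
            "AAAGG": {("p1", "F"): 1, ("p2", "F"): 0, ("p1", "M"): 30, ("p2", "M"): 30},
            "AAATT": {("p1", "F"): 0, ("p2", "F"): 0, ("p1", "M"): 2, ("p2", "M"): 30},
            "AATTC": {("p1", "F"): 0, ("p2", "F"): 0, ("p1", "M"): 25, ("p2", "M"): 25},
        })
        # p1 male mean = (30+30+2+25)/4 = 21.75; p2 male mean = 28.75
        ys = ymer.call_conserved_ymers(m)
        got = {ymer.decode_kmer(int(c), 5) for c in ys.codes}
        assert got == {"AAACC", "AAATT"} - {"AAATT"}  # AAATT fails p1 mean
        assert ys.contains("AAACC")
        assert not ys.contains("AAAGG")

    def test_empty_matrix_gives_empty_set(self):
        m = KmerCountMatrix(5, np.zeros(0, np.uint64),
                            np.zeros((0, 2), np.int64),
                            [("p1", "F"), ("p1", "M")])
        assert len(ymer.call_conserved_ymers(m)) == 0


class TestReadSelection:
    def _ymers(self, kmers: list[str], k: int) -> YmerSet:
        codes = np.array(sorted(ymer.canonical_code(ymer.encode_kmer(s), k)
                                for s in kmers), dtype=np.uint64)
        return YmerSet(k, codes)

    def test_reverse_complement_match_selects(self):
        ys = self._ymers(["ACGTTGCA"], 8)
        r1 = [dna.revcomp_str("ACGTTGCA") + "TTTT"]
        r2 = ["AAAAAAAAAAAA"]
        assert ymer.select_ymer_reads(r1, r2, ys).tolist() == [True]

    def test_mate_hit_selects_whole_pair(self):
        ys = self._ymers(["ACGTTGCA"], 8)
        r1 = ["AAAAAAAAAAAA"]
        r2 = ["GGACGTTGCAGG"]
        assert ymer.select_ymer_reads(r1, r2, ys).tolist() == [True]

    def test_membership_matches_substring_oracle(self):
        rng = np.random.default_rng(17)
        k = 9
        reads = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(300)]
        kmers = [r[5:5 + k] for r in reads[::17]]
        ys = self._ymers(kmers, k)
        mask = ymer.select_ymer_reads(reads, ["A" * 40] * len(reads), ys)
        targets = {min(s, dna.revcomp_str(s)) for s in kmers}
        expected = [
            any(min(r[i:i + k], dna.revcomp_str(r[i:i + k])) in targets
                for i in range(len(r) - k + 1))
            for r in reads
        ]
        assert mask.tolist() == expected

    def test_empty_ymer_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            ymer.select_ymer_reads(["ACGT"], ["ACGT"], YmerSet(3, np.zeros(0, np.uint64)))


class TestAssembly:
    def test_recovers_planted_sequence(self):
        """Error-free reads tiling a 2-kb random sequence at ~20x assemble
        into a single contig equal to it (up to strand)."""
        rng = np.random.default_rng(23)
        seq = dna.decode(dna.random_seq(rng, 2000))
        reads = [seq[i:i + 100] for i in range(0, 1901, 5)]
        contigs = ymer.assemble_contigs(reads * 2, assembly_k=31, min_unitig_cov=2)
        assert len(contigs) == 1
        assert contigs[0] in (seq, dna.revcomp_str(seq))

    def test_snp_bubble_breaks_contig(self):
        """Two haplotypes differing at one SNP produce a bubble: >= 2
        contigs span the locus instead of one."""
        rng = np.random.default_rng(29)
        hap_a = dna.decode(dna.random_seq(rng, 600))
        hap_b = hap_a[:300] + ("A" if hap_a[300] != "A" else "C") + hap_a[301:]
        reads = []
        for hap in (hap_a, hap_b):
            reads += [hap[i:i + 80] for i in range(0, 521, 4)]
        contigs = ymer.assemble_contigs(reads * 2, assembly_k=21, min_unitig_cov=2)
        assert len(contigs) >= 2

    def test_single_short_read_yields_nothing(self, caplog):
        with caplog.at_level("WARNING"):
            assert ymer.assemble_contigs(["ACGTACGT"], assembly_k=31) == []

    def test_deterministic(self):
        rng = np.random.default_rng(31)
        seq = dna.decode(dna.random_seq(rng, 500))
        reads = [seq[i:i + 60] for i in range(0, 441, 3)] * 3
        a = ymer.assemble_contigs(reads, assembly_k=21, min_unitig_cov=2)
        b = ymer.assemble_contigs(reads, assembly_k=21, min_unitig_cov=2)
        assert a == b and a


class TestPlacement:
    @pytest.fixture()
    def reference(self):
        rng = np.random.default_rng(37)
        return {"chrA": dna.random_seq(rng, 30_000),
                "chrB": dna.random_seq(rng, 30_000)}

    def test_verbatim_copy_places_at_origin(self, reference):
        contig = dna.decode(reference["chrB"][5_000:6_200])
        out = ymer.place_contigs([contig], reference)
        row = out.iloc[0]
        assert (row["chrom"], row["start"], row["strand"]) == ("chrB", 5_000, "+")
        assert row["end"] == 6_200

    def test_reverse_complement_places_same_interval_minus(self, reference):
        contig = dna.revcomp_str(dna.decode(reference["chrB"][5_000:6_200]))
        out = ymer.place_contigs([contig], reference)
        row = out.iloc[0]
        assert (row["chrom"], row["start"], row["end"], row["strand"]) == \
            ("chrB", 5_000, 6_200, "-")

    def test_random_contig_is_unplaced(self, reference):
        rng = np.random.default_rng(41)
        contig = dna.decode(dna.random_seq(rng, 1000))
        out = ymer.place_contigs([contig], reference)
        assert out["chrom"].isna().iloc[0]

    def test_tie_breaks_to_lowest_coordinate(self):
        """A contig present verbatim at two loci goes to the lower one."""
        rng = np.random.default_rng(43)
        block = dna.random_seq(rng, 800)
        genome = np.concatenate([dna.random_seq(rng, 2_000), block,
                                 dna.random_seq(rng, 4_000), block,
                                 dna.random_seq(rng, 2_000)])
        out = ymer.place_contigs([dna.decode(block)], {"chr": genome})
        assert out.iloc[0]["start"] == 2_000


class TestRecruitment:
    def test_midpoints_bin_together(self):
        placements = pd.DataFrame({
            "contig_index": [0, 1], "length": [500, 600],
            "chrom": ["chrA", "chrA"], "start": [24_810_000, 24_850_000],
            "end": [24_810_500, 24_850_600], "strand": ["+", "-"],
            "score": [500.0, 600.0], "population": ["p1", "p1"]})
        out = ymer.recruitment_by_window(placements, {"chrA": 25_000_000})
        hit = out[(out["start"] <= 24_810_000) & (out["end"] > 24_810_000)]
        assert hit["p1"].iloc[0] == 2

    def test_no_placements_all_zero(self):
        out = ymer.recruitment_by_window(
            pd.DataFrame(columns=["contig_index", "length", "chrom", "start",
                                  "end", "strand", "score", "population"]),
            {"chr1": 300_000})
        assert (out["chrom_length_share"] == 0).all()

    def test_counts_match_brute_force_binning(self):
        rng = np.random.default_rng(47)
        n = 60
        placements = pd.DataFrame({
            "contig_index": range(n), "length": 400,
            "chrom": rng.choice(["c1", "c2"], n),
            "start": rng.integers(0, 900_000, n),
            "strand": "+", "score": 1.0,
            "population": rng.choice(["p1", "p2"], n)})
        placements["end"] = placements["start"] + 400
        out = ymer.recruitment_by_window(placements, {"c1": 1_000_000,
                                                      "c2": 1_000_000})
        for _, row in placements.iterrows():
            mid = (row["start"] + row["end"]) // 2
            w = out[(out["chrom"] == row["chrom"]) & (out["start"] <= mid)
                    & (mid < out["end"])]
            naive = ((placements["chrom"] == row["chrom"])
                     & (placements["population"] == row["population"])
                     & ((placements["start"] + placements["end"]) // 2 >= w["start"].iloc[0])
                     & ((placements["start"] + placements["end"]) // 2 < w["end"].iloc[0])).sum()
            assert w[row["population"]].iloc[0] == naive
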