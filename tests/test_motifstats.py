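import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from polyterm import annotation, motifstats as ms
from polyterm.intervals import Genome, GenomicInterval, reverse_complement
from polyterm.readthrough import PasSite

DNA = st.text(alphabet="ACGT", min_size=5, max_size=120)


def oracle_positions(seq, motif):
    return [i for i in range(len(seq) - len(motif) + 1)
            if seq[i:i + len(motif)] == motif]


def oracle_corrected(seq, motif, w=0.2):
    """Chain-grouping oracle on enumerated positions."""
    pos = oracle_positions(seq, motif)
    total = 0.0
    prev = None
    for p in pos:
        if prev is not None and p - prev < len(motif):
            total += w
        else:
            total += 1.0
        prev = p
    return total


class TestOverlapCounting:
    @pytest.mark.parametrize("seq,motif,expected", [
        ("TTTTT", "TTTT", 2),   # five T's hold two overlapping TTTT hits
        ("ACGT", "ACGT", 1),
        ("ACACAC", "ACA", 2),
    ])
    def test_examples(self, seq, motif, expected):
        assert ms.count_overlapping_motif(seq, motif) == expected

    @given(DNA, st.text(alphabet="ACGT", min_size=1, max_size=5))
    def test_matches_position_enumeration(self, seq, motif):
        assert ms.count_overlapping_motif(seq, motif) == \
            len(oracle_positions(seq, motif))


class TestCorrectedCounts:
    def test_run_of_six_counts_1_2(self):
        assert ms.corrected_kmer_counts("TTTTTT")["TTTTT"] == \
            pytest.approx(1.2)

    def test_single_instance_counts_one(self):
        assert ms.corrected_kmer_counts("TTTTT")["TTTTT"] == 1.0

    def test_two_disjoint_chains(self):
        assert ms.corrected_kmer_counts("TTTTTCGTTTTT")["TTTTT"] == \
            pytest.approx(2.0)

    def test_run_length_formula(self):
        # a single maximal run of length L >= k counts 1 + 0.2*(L - k)
        for L in range(5, 15):
            counts = ms.corrected_kmer_counts("A" * L)
            assert counts["AAAAA"] == pytest.approx(1 + 0.2 * (L - 5))

    @given(DNA)
    def test_equals_chain_oracle_per_motif(self, seq):
        counts = ms.corrected_kmer_counts(seq)
        for motif in set(seq[i:i + 5] for i in range(len(seq) - 4)):
            assert counts[motif] == pytest.approx(oracle_corrected(seq, motif))

    @given(DNA)
    def test_corrected_at_most_raw(self, seq):
        counts = ms.corrected_kmer_counts(seq)
        for motif, val in counts.items():
            raw = ms.count_overlapping_motif(seq, motif)
            assert val <= raw + 1e-12
            if all(b - a >= 5 for a, b in
                   zip(oracle_positions(seq, motif),
                       oracle_positions(seq, motif)[1:])):
                assert val == pytest.approx(raw)


def _pas_setup(pas_offset=500, strand="+"):
    """One gene whose terminal intron acceptor sits a known distance
    upstream of the PAS."""
    fs = annotation.FeatureSet()
    if strand == "+":
        fs.introns["g"] = [GenomicInterval("c", 900, 1000, "+")]
        site = PasSite("p", GenomicInterval(
            "c", 1000 + pas_offset - 1, 1000 + pas_offset, "+"))
    else:
        fs.introns["g"] = [GenomicInterval("c", 9000, 9100, "-")]
        site = PasSite("p", GenomicInterval(
            "c", 9000 - pas_offset, 9000 - pas_offset + 1, "-"))
    return fs, site


class TestBuildWindows:
    def test_pas_window_length(self):
        fs, site = _pas_setup(pas_offset=500)
        windows, excl = ms.build_pas_windows([site], fs, {"c": 100_000})
        assert excl == 0
        [w] = windows
        assert len(w.region) == 200 + 500 + 200
        assert len(w.upstream) == 200 and len(w.downstream) == 200
        assert len(w.body) == 500

    def test_minus_strand_geometry(self):
        fs, site = _pas_setup(pas_offset=500, strand="-")
        windows, excl = ms.build_pas_windows([site], fs, {"c": 100_000})
        [w] = windows
        assert len(w.region) == 900
        # upstream flank lies at higher coordinates on the minus strand
        assert w.upstream.start > w.body.start
        assert w.downstream.end <= w.body.start + 1

    def test_exon_window_length(self):
        exons = {"e": GenomicInterval("c", 1000, 1100, "+")}
        [w] = ms.build_exon_windows(exons, {"c": 100_000})
        assert len(w.region) == 500

    def test_single_exon_gene_excluded(self):
        fs = annotation.FeatureSet()  # no introns -> no acceptor
        site = PasSite("p", GenomicInterval("c", 1000, 1001, "+"))
        windows, excl = ms.build_pas_windows([site], fs, {"c": 100_000})
        assert windows == [] and excl == 1


def brute_force_spearman(x, y):
    """Independent rank-based implementation: ranks by sorting with
    midrank ties, then the explicit Pearson sum formula."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx)
           * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


class TestMotifCorrelation:
    def _windows_and_genome(self, seqs):
        chunks, windows, pos = [], [], 0
        for i, s in enumerate(seqs):
            chunks.append(s)
            iv = GenomicInterval("c", pos, pos + len(s), "+")
            windows.append(ms.AnalysisWindow(f"r{i}", iv, None, iv, None))
            pos += len(s)
        return windows, Genome({"c": "".join(chunks)})

    def test_perfect_antitone_rho_minus_one(self):
        seqs = ["CAGCAGCAGCAGCAGCAGCG",
                "TTTTTGCAGCAGCAGCAGCG",
                "TTTTTGTTTTTGCAGCAGCG",
                "TTTTTGTTTTTGTTTTTGCG"]
        windows, genome = self._windows_and_genome(seqs)
        fold = {f"r{i}": fc for i, fc in enumerate([8.0, 4.0, 2.0, 1.0])}
        res = ms.motif_correlation(windows, fold, genome).set_index("motif")
        assert res.loc["TTTTT", "spearman_rho"] == pytest.approx(-1.0)
        assert res.loc["TTTTT", "p_value"] < 0.05

    def test_motif_universe_is_complete(self):
        windows, genome = self._windows_and_genome(["ACGTA" * 10] * 3)
        res = ms.motif_correlation(windows, {f"r{i}": 1.0 + i * 0.1
                                             for i in range(3)}, genome)
        assert len(res) == 4 ** 5
        assert res.motif.is_unique

    def test_absent_motif_flagged(self):
        windows, genome = self._windows_and_genome(["ACGTA" * 10] * 3)
        res = ms.motif_correlation(windows, {f"r{i}": 1.0 + i * 0.1
                                             for i in range(3)},
                                   genome).set_index("motif")
        assert bool(res.loc["GGGGG", "absent"])
        assert np.isnan(res.loc["GGGGG", "spearman_rho"])

    def test_matches_scipy_and_brute_force(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(50)]
        windows, genome = self._windows_and_genome(seqs)
        fold = {f"r{i}": float(rng.lognormal(0, 0.5)) for i in range(50)}
        res = ms.motif_correlation(windows, fold, genome).set_index("motif")
        y = [np.log2(fold[f"r{i}"]) for i in range(50)]
        for motif in ("TTTTT", "ACGTA", "GGGGG", "AATAA"):
            freqs = [ms.corrected_kmer_counts(s).get(motif, 0.0) / len(s)
                     for s in seqs]
            if sum(freqs) == 0:
                continue
            rho = res.loc[motif, "spearman_rho"]
            assert rho == pytest.approx(
                brute_force_spearman(freqs, y), abs=1e-12)
            sp_rho, sp_p = stats.spearmanr(freqs, y)
            assert rho == pytest.approx(sp_rho, abs=1e-12)
            assert res.loc[motif, "p_value"] == pytest.approx(sp_p, rel=1e-6)

    def test_reverse_complement_pairing(self):
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(30)]
        fold = {f"r{i}": float(rng.lognormal(0, 0.5)) for i in range(30)}
        plus_windows, genome = self._windows_and_genome(seqs)
        # mirrored records: same sequences presented on the minus strand
        minus_seqs = [reverse_complement(s) for s in seqs]
        chunks, minus_windows, pos = [], [], 0
        for i, s in enumerate(minus_seqs):
            iv = GenomicInterval("c", pos, pos + len(s), "-")
            minus_windows.append(ms.AnalysisWindow(f"r{i}", iv, None, iv, None))
            chunks.append(s)
            pos += len(s)
        genome_minus = Genome({"c": "".join(chunks)})
        res_p = ms.motif_correlation(plus_windows, fold,
                                     genome).set_index("motif")
        res_m = ms.motif_correlation(minus_windows, fold,
                                     genome_minus).set_index("motif")
        for motif in ("TTTTT", "ACGTA", "TTAGC"):
            a = res_p.loc[motif, "spearman_rho"]
            b = res_m.loc[motif, "spearman_rho"]
            if np.isnan(a):
                assert np.isnan(b)
            else:
                assert a == pytest.approx(b, abs=1e-12)

    def test_needs_three_records(self):
        windows, genome = self._windows_and_genome(["ACGTA" * 10] * 2)
        with pytest.raises(ValueError):
            ms.motif_correlation(windows, {"r0": 1.0, "r1": 2.0}, genome)


class TestAtProfile:
    def test_all_AT_group(self):
        genome = Genome({"c": "AT" * 200})
        sites = [PasSite("p", GenomicInterval("c", 200, 201, "+"))]
        df = ms.at_content_profile({"g": sites}, genome)
        assert np.allclose(df["g"], 1.0)

    def test_uniform_random_near_half(self):
        rng = np.random.default_rng(0)
        genome = Genome({"c": "".join(rng.choice(list("ACGT"), 50_000))})
        sites = [PasSite(f"p{i}", GenomicInterval("c", int(p), int(p) + 1, "+"))
                 for i, p in enumerate(rng.integers(100, 49_900, 300))]
        df = ms.at_content_profile({"g": sites}, genome)
        assert ((df["g"] - 0.5).abs() < 0.12).all()  # 4 sigma at n=300

    def test_planted_core_localized(self):
        rng = np.random.default_rng(1)
        chunks, sites, pos = [], [], 0
        for i in range(100):
            s = list("".join(rng.choice(list("GC"), 200)))
            # A-rich stretch at offsets -30..-20 relative to the site (at 100)
            s[70:80] = "A" * 10
            chunks.append("".join(s))
            sites.append(PasSite(
                f"p{i}", GenomicInterval("c", pos + 100, pos + 101, "+")))
            pos += 200
        genome = Genome({"c": "".join(chunks)})
        df = ms.at_content_profile({"g": sites}, genome).set_index("position")
        assert (df.loc[-30:-21, "g"] == 1.0).all()
        assert df.loc[0:50, "g"].mean() < 0.05

    def test_minus_strand_orientation(self):
        # A-rich block upstream (higher coordinates) of a minus-strand PAS
        genome = Genome({"c": "G" * 100 + "A" * 10 + "G" * 100})
        site = PasSite("p", GenomicInterval("c", 90, 91, "-"))
        df = ms.at_content_profile({"g": [site]}, genome).set_index("position")
        # upstream positions are negative; the A block sits 10-19 upstream
        assert (df.loc[-19:-10, "g"] == 1.0).all()
        assert df.loc[0:50, "g"].sum() == 0


class TestCompareCorrelations:
    def test_identical_and_opposite(self):
        rng = np.random.default_rng(0)
        rho = pd.Series(rng.uniform(-1, 1, 100),
                        index=[f"m{i}" for i in range(100)])
        r, _ = ms.compare_correlations(rho, rho)
        assert r == pytest.approx(1.0)
        r, _ = ms.compare_correlations(rho, -rho)
        assert r == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(1)
        idx = [f"m{i}" for i in range(1024)]
        a = pd.Series(rng.standard_normal(1024), index=idx)
        b = pd.Series(rng.standard_normal(1024), index=idx)
        r, _ = ms.compare_correlations(a, b)
        assert abs(r) < 0.1

    def test_undefined_dropped_and_minimum(self):
        a = pd.Series([0.1, np.nan, 0.3], index=list("abc"))
        b = pd.Series([0.2, 0.5, np.nan], index=list("abc"))
        with pytest.raises(ValueError):
            ms.compare_correlations(a, b)
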