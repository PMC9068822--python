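import numpy as np
import pandas as pd
import pytest
from _oracles import intersect_intervals_naive, merge_intervals_naive

from fluxmark.chromatin import (
    CutCountMatrix,
    FeatureSet,
    GenomicInterval,
    PeakSet,
    count_cut_sites,
    cpm_normalize,
    feature_enrichment,
    intersect_peaks,
    merge_peaks,
    read_bed,
    shift_cut_sites,
    tss_windows,
    write_bed,
)

GENOME = {"chr1": 100_000, "chr2": 50_000}


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def peaks(*triples, name="p", genome=GENOME):
    return PeakSet(name, [iv(*t) for t in triples], genome)


def random_set(rng, n, name):
    ivs = []
    for _ in range(n):
        chrom = "chr1" if rng.uniform() < 0.7 else "chr2"
        start = int(rng.integers(0, GENOME[chrom] - 200))
        ivs.append(iv(chrom, start, start + int(rng.integers(1, 200))))
    return PeakSet(name, ivs, GENOME)


class TestIntervalModel:
    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            peaks(("chr2", 0, 60_000))

    def test_bed_round_trip(self, tmp_path):
        ps = peaks(("chr1", 10, 20), ("chr2", 5, 500))
        path = tmp_path / "x.bed"
        write_bed(ps, path)
        back = read_bed(path, GENOME)
        assert back.intervals == ps.intervals


class TestMergeIntersect:
    def test_overlapping_pair_merges(self):
        merged = merge_peaks([peaks(("chr1", 10, 20), ("chr1", 15, 30))])
        assert merged.intervals == [iv("chr1", 10, 30)]

    def test_bookended_intervals_coalesce(self):
        merged = merge_peaks([peaks(("chr1", 0, 5), ("chr1", 5, 10))])
        assert merged.intervals == [iv("chr1", 0, 10)]

    def test_disjoint_unchanged(self):
        merged = merge_peaks([peaks(("chr1", 0, 5), ("chr1", 10, 15))])
        assert merged.intervals == [iv("chr1", 0, 5), iv("chr1", 10, 15)]

    def test_intersection_basic(self):
        out = intersect_peaks(peaks(("chr1", 10, 20)), peaks(("chr1", 15, 30)))
        assert out.intervals == [iv("chr1", 15, 20)]

    def test_disjoint_intersection_empty(self):
        out = intersect_peaks(peaks(("chr1", 0, 5)), peaks(("chr1", 10, 15)))
        assert out.intervals == []

    def test_genome_mismatch_rejected(self):
        other = PeakSet("o", [iv("chrX", 0, 10)], {"chrX": 100})
        with pytest.raises(ValueError, match="genome mismatch"):
            merge_peaks([peaks(("chr1", 0, 5)), other])

    @pytest.mark.parametrize("seed", range(10))
    def test_merge_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sets = [random_set(rng, 100, f"s{i}") for i in range(3)]
        merged = merge_peaks(sets)
        triples = [(i.chrom, i.start, i.end) for s in sets for i in s.intervals]
        assert [(i.chrom, i.start, i.end) for i in merged.intervals] == merge_intervals_naive(
            triples
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_intersect_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = random_set(rng, 60, "a"), random_set(rng, 60, "b")
        # naive pairwise output can contain duplicates/overlaps; merge both sides
        got = merge_peaks([intersect_peaks(a, b)])
        want = merge_intervals_naive(
            intersect_intervals_naive(
                [(i.chrom, i.start, i.end) for i in a.intervals],
                [(i.chrom, i.start, i.end) for i in b.intervals],
            )
        )
        assert [(i.chrom, i.start, i.end) for i in got.intervals] == want


class TestTssWindows:
    def test_symmetric_window(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [5000], "strand": ["+"]})
        fs = tss_windows(tss, GENOME, flank=1000)
        assert fs.intervals == [iv("chr1", 4000, 6000)]

    def test_clipped_at_chromosome_start(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "pos": [300], "strand": ["-"]})
        fs = tss_windows(tss, GENOME, flank=1000)
        assert fs.intervals == [iv("chr1", 0, 1300)]

    def test_multiple_tss_per_gene_all_kept(self):
        tss = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [5000, 9000],
             "strand": ["+", "+"], "gene_id": ["g1", "g1"]}
        )
        assert len(tss_windows(tss, GENOME)) == 2

    def test_position_outside_genome_rejected(self):
        tss = pd.DataFrame({"chrom": ["chr2"], "pos": [60_000], "strand": ["+"]})
        with pytest.raises(ValueError, match="outside genome"):
            tss_windows(tss, GENOME)


class TestFeatureEnrichment:
    def test_worked_arithmetic_example(self):
        # G=1e6; 100 peaks of 500 bp; 10 features of 1500 bp; 50 overlap:
        # d = 1e6/2000 = 500 and enrichment = (50/100)/(10/500) = 25.0
        genome = {"chr1": 1_000_000}
        feats = FeatureSet(
            "f", [iv("chr1", 10_000 * i, 10_000 * i + 1500) for i in range(10)], genome
        )
        ivs = [iv("chr1", 10_000 * (i % 10) + 500 + 10 * (i // 10),
                  10_000 * (i % 10) + 1000 + 10 * (i // 10))
               for i in range(50)]  # 50 distinct peaks inside the features
        ivs += [iv("chr1", 500_000 + 600 * i, 500_000 + 600 * i + 500)
                for i in range(50)]  # 50 clear of all features
        res = feature_enrichment(PeakSet("p", ivs, genome), feats)
        assert (res.a, res.b, res.c) == (50, 100, 10)
        assert res.d == pytest.approx(500.0)
        assert res.enrichment == pytest.approx(25.0)

    def test_peaks_equal_features_reduces_to_d_over_c(self):
        genome = {"chr1": 100_000}
        ivs = [iv("chr1", 1000 * i, 1000 * i + 200) for i in range(5)]
        res = feature_enrichment(PeakSet("p", ivs, genome), FeatureSet("f", ivs, genome))
        assert res.enrichment == pytest.approx(res.d / res.c)

    def test_whole_genome_feature_reduces_to_d(self):
        genome = {"chr1": 100_000}
        ps = peaks(("chr1", 10, 510), ("chr1", 5000, 5500), genome=genome)
        whole = FeatureSet("w", [iv("chr1", 0, 100_000)], genome)
        res = feature_enrichment(ps, whole)
        assert res.a == res.b == 2 and res.c == 1
        assert res.enrichment == pytest.approx(res.d)

    def test_empty_sets_rejected(self):
        ps = peaks(("chr1", 0, 10))
        empty = FeatureSet("e", [], GENOME)
        with pytest.raises(ValueError, match="undefined enrichment"):
            feature_enrichment(ps, empty)
        with pytest.raises(ValueError, match="undefined enrichment"):
            feature_enrichment(empty, ps)

    def test_invariant_to_chromosome_relabeling_and_shift(self):
        genome_a = {"chr1": 100_000, "chr2": 50_000}
        genome_b = {"alpha": 100_000, "beta": 50_000}
        pk = [("chr1", 100, 600), ("chr2", 7000, 7400)]
        ft = [("chr1", 0, 2000), ("chr2", 40_000, 41_000)]
        res_a = feature_enrichment(
            PeakSet("p", [iv(*t) for t in pk], genome_a),
            FeatureSet("f", [iv(*t) for t in ft], genome_a),
        )
        relabel = {"chr1": "alpha", "chr2": "beta"}
        res_b = feature_enrichment(
            PeakSet("p", [iv(relabel[c], s + 100, e + 100) for c, s, e in pk], genome_b),
            FeatureSet("f", [iv(relabel[c], s + 100, e + 100) for c, s, e in ft], genome_b),
        )
        assert res_a.enrichment == pytest.approx(res_b.enrichment)


class TestCutCounting:
    def test_counts_positions_inside_peaks(self):
        ps = peaks(("chr1", 10, 20))
        cuts = {"s1": pd.DataFrame({"chrom": ["chr1"] * 4, "pos": [10, 15, 19, 25]})}
        m = count_cut_sites(cuts, ps)
        assert m.counts.loc["chr1:10-20", "s1"] == 3

    def test_unknown_chromosome_skipped_and_tallied(self):
        ps = peaks(("chr1", 10, 20))
        cuts = {"s1": pd.DataFrame({"chrom": ["chrM", "chr1"], "pos": [5, 12]})}
        m = count_cut_sites(cuts, ps)
        assert m.skipped["s1"] == 1
        assert m.counts["s1"].sum() == 1

    def test_empty_peak_set_gives_zero_rows(self):
        m = count_cut_sites({"s1": pd.DataFrame({"chrom": [], "pos": []})},
                            PeakSet("p", [], GENOME))
        assert m.counts.shape == (0, 1)

    def test_tn5_shift(self):
        pos = shift_cut_sites(np.array([100, 100]), np.array(["+", "-"]))
        assert list(pos) == [104, 95]

    def test_poisson_intensities_recovered(self):
        from fluxmark.synthetic import SyntheticConfig, simulate_peaks_and_features

        cfg = SyntheticConfig(seed=9, n_peaks=200)
        pk, _, cuts, truth = simulate_peaks_and_features(cfg)
        m = count_cut_sites(cuts, pk)
        lam = truth["lam"].to_numpy()
        counts = m.counts["s1"].to_numpy()
        # the per-peak plan is exact only for peaks that overlap no other
        # peak (overlapping peaks also collect their neighbour's cuts)
        isolated = np.array(
            [
                sum(
                    1
                    for other in pk.intervals
                    if other.chrom == p.chrom and other.start < p.end and p.start < other.end
                )
                == 1
                for p in pk.intervals
            ]
        )
        assert isolated.sum() > 100  # most peaks are isolated at this density
        z = (counts[isolated] - lam[isolated]) / np.sqrt(lam[isolated])
        assert abs(z.mean()) < 0.25
        assert (np.abs(z) < 5).all()


class TestCpm:
    def test_direct_arithmetic(self):
        m = CutCountMatrix(pd.DataFrame({"s1": [10, 90]}, index=["a", "b"]))
        out = cpm_normalize(m)
        assert list(out["s1"]) == [1e5, 9e5]

    def test_all_zero_column_stays_zero(self):
        m = CutCountMatrix(pd.DataFrame({"s1": [0, 0], "s2": [1, 1]}, index=["a", "b"]))
        out = cpm_normalize(m)
        assert list(out["s1"]) == [0.0, 0.0]
        assert out["s2"].sum() == pytest.approx(1e6)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(2)
        m = CutCountMatrix(
            pd.DataFrame(rng.integers(0, 50, size=(30, 3)), columns=list("abc"))
        )
        out = cpm_normalize(m)
        assert np.allclose(out.sum(axis=0), 1e6)
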