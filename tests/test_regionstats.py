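import math

import numpy as np
import pytest

from methconc.canyons import CpGMethTrack
from methconc.io import GeneModel, GenomicInterval
from methconc.regionstats import (
    binned_matrix,
    classify_interactions,
    cpk,
    motif_fold_enrichment,
    per_bin_correlation,
    shuffle_regions,
    tf_odds_ratio,
)


def iv(start, end, chrom="chr1", name=None):
    return GenomicInterval(chrom, start, end, name=name)


def flat_track(start, n, value, spacing=50, coverage=10):
    return CpGMethTrack(
        "chr1",
        np.arange(start, start + n * spacing, spacing),
        np.full(n, float(value)),
        np.full(n, coverage),
    )


class TestBinnedMatrix:
    def test_plus_strand_bin_windows(self):
        # single CpG at TSS-1950 (bin 0) with methylation 0.8
        gene = GeneModel("g", "chr1", "+", tss=100_000, tts=200_000)
        t = CpGMethTrack("chr1", np.array([98_050]), np.array([0.8]),
                         np.array([10]))
        mat = binned_matrix({"chr1": t}, [gene])
        assert mat.shape == (1, 120)
        assert mat.iloc[0, 0] == pytest.approx(0.8)
        assert mat.iloc[0, 1:].isna().all()

    def test_minus_strand_bin_zero_lies_downstream_genomically(self):
        # for a '-' gene, oriented offset -2 kb maps to genomic TSS + 2 kb
        gene = GeneModel("g", "chr1", "-", tss=100_000, tts=50_000)
        t = CpGMethTrack("chr1", np.array([101_950]), np.array([0.6]),
                         np.array([10]))
        mat = binned_matrix({"chr1": t}, [gene])
        assert mat.iloc[0, 0] == pytest.approx(0.6)

    def test_bin_value_is_coverage_weighted(self):
        gene = GeneModel("g", "chr1", "+", tss=10_000, tts=50_000)
        t = CpGMethTrack(
            "chr1", np.array([8_010, 8_020]), np.array([0.0, 1.0]),
            np.array([10, 30]),
        )
        mat = binned_matrix({"chr1": t}, [gene])
        assert mat.iloc[0, 0] == pytest.approx(0.75)

    def test_low_coverage_cpgs_excluded(self):
        gene = GeneModel("g", "chr1", "+", tss=10_000, tts=50_000)
        t = CpGMethTrack("chr1", np.array([8_010]), np.array([1.0]),
                         np.array([3]))
        mat = binned_matrix({"chr1": t}, [gene], coverage_min=4)
        assert mat.iloc[0].isna().all()


class TestPerBinCorrelation:
    @staticmethod
    def matrix_and_expression(column):
        import pandas as pd

        genes = [f"g{i}" for i in range(len(column))]
        mat = pd.DataFrame({0: column}, index=genes)
        expr = {g: float(i) for i, g in enumerate(genes)}
        return mat, expr

    def test_identical_ranks_give_one(self):
        mat, expr = self.matrix_and_expression(np.linspace(0, 1, 12))
        assert per_bin_correlation(mat, expr)[0] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        mat, expr = self.matrix_and_expression(np.linspace(1, 0, 12))
        assert per_bin_correlation(mat, expr)[0] == pytest.approx(-1.0)

    def test_constant_bin_is_missing(self):
        mat, expr = self.matrix_and_expression(np.full(12, 0.5))
        assert np.isnan(per_bin_correlation(mat, expr)[0])

    def test_gene_floor_enforced(self):
        mat, expr = self.matrix_and_expression(np.linspace(0, 1, 5))
        assert np.isnan(per_bin_correlation(mat, expr, min_genes=10)[0])


class TestCpk:
    def test_counts_per_kilobase(self):
        hits = [iv(s, s + 10) for s in (100, 200, 300, 400, 500)]
        assert cpk(hits, [iv(0, 2000)]) == pytest.approx(2.5)

    def test_no_hits_zero(self):
        assert cpk([], [iv(0, 1000)]) == 0.0

    def test_membership_by_midpoint(self):
        straddler = iv(990, 1010)  # midpoint 1000, outside [0,1000)
        assert cpk([straddler], [iv(0, 1000)]) == 0.0
        assert cpk([straddler], [iv(1000, 2000)]) == pytest.approx(1.0)

    def test_invariant_under_region_split(self):
        hits = [iv(s, s + 2) for s in (10, 500, 900)]
        whole = cpk(hits, [iv(0, 1000)])
        halves = cpk(hits, [iv(0, 500), iv(500, 1000)])
        assert whole == pytest.approx(halves)

    def test_zero_length_region_set_rejected(self):
        with pytest.raises(ValueError):
            cpk([], [])


class TestMotifEnrichment:
    def test_log2_fold(self):
        a, p = [iv(0, 1000)], [iv(10_000, 11_000)]
        hits = {"m1": [iv(i * 10, i * 10 + 2) for i in range(4)]
                + [iv(10_100, 10_102)]}
        rows, _, _ = motif_fold_enrichment(hits, a, p, {"m1": 1.0})
        assert rows[0].log2_fold == pytest.approx(2.0)  # CPK 4 vs 1
        assert rows[0].klass == "methyl-plus"

    def test_pseudocount_on_zero_flagged(self):
        a, p = [iv(0, 1000)], [iv(10_000, 11_000)]
        hits = {"m1": [iv(100, 102)]}
        rows, _, _ = motif_fold_enrichment(hits, a, p, {"m1": -0.5})
        assert rows[0].pseudocount
        assert rows[0].log2_fold == pytest.approx(1.0)  # (1+1)/(0+1)

    def test_planted_preference_direction(self):
        # methyl-minus motifs planted 2x denser in aCanyons and vice versa:
        # fold correlates negatively with preference
        rng = np.random.default_rng(8)
        a = [iv(i * 10_000, i * 10_000 + 2000) for i in range(5)]
        p = [iv(1_000_000 + i * 10_000, 1_002_000 + i * 10_000) for i in range(5)]
        hits, prefs = {}, {}
        for m in range(20):
            pref = -1.0 + 0.1 * m  # half minus, half plus
            prefs[f"m{m}"] = pref
            dense, sparse = (a, p) if pref < 0 else (p, a)
            hs = []
            for region in dense:
                hs += [iv(int(x), int(x) + 2) for x in
                       rng.integers(region.start, region.end - 2, 8)]
            for region in sparse:
                hs += [iv(int(x), int(x) + 2) for x in
                       rng.integers(region.start, region.end - 2, 4)]
            hits[f"m{m}"] = hs
        _, rho, _ = motif_fold_enrichment(hits, a, p, prefs)
        assert rho < -0.5


class TestTfOdds:
    a = [iv(0, 1000), iv(2000, 3000), iv(4000, 5000), iv(6000, 7000)]
    p = [iv(10_000, 11_000), iv(12_000, 13_000), iv(14_000, 15_000),
         iv(16_000, 17_000)]

    def test_ratio_of_occupied_fractions(self):
        peaks = [iv(100, 200), iv(2100, 2200), iv(10_100, 10_200)]
        assert tf_odds_ratio(peaks, self.a, self.p) == pytest.approx(2.0)

    def test_equal_occupancy_is_one(self):
        peaks = [iv(100, 200), iv(10_100, 10_200)]
        assert tf_odds_ratio(peaks, self.a, self.p) == pytest.approx(1.0)

    def test_unoccupied_pcanyons_give_infinity(self):
        peaks = [iv(100, 200)]
        assert tf_odds_ratio(peaks, self.a, self.p) == math.inf

    def test_shuffle_control_near_unity_for_random_peaks(self):
        rng = np.random.default_rng(17)
        sizes = {"chr1": 10_000_000}
        regions_a = shuffle_regions([iv(0, 5000)] * 40, sizes, seed=1)
        regions_p = shuffle_regions([iv(0, 5000)] * 40, sizes, seed=2)
        peaks = [iv(int(x), int(x) + 200)
                 for x in rng.integers(0, 9_999_000, 3000)]
        ratio = tf_odds_ratio(peaks, regions_a, regions_p)
        assert 0.7 < ratio < 1.4


class TestInteractions:
    regions = [iv(0, 5000, name="X"), iv(100_000, 105_000, name="Y")]

    def test_same_region_is_self_interacting(self):
        pairs = [(iv(100, 200), iv(4000, 4100))]
        assert classify_interactions(pairs, self.regions) == ["self-interacting"]

    def test_two_different_regions_is_distant(self):
        pairs = [(iv(100, 200), iv(100_100, 100_200))]
        assert classify_interactions(pairs, self.regions) == ["distant-interacting"]

    def test_one_anchor_in_region_is_distant(self):
        pairs = [(iv(100, 200), iv(50_000, 50_100))]
        assert classify_interactions(pairs, self.regions) == ["distant-interacting"]

    def test_neither_anchor_is_none(self):
        pairs = [(iv(50_000, 50_100), iv(60_000, 60_100))]
        assert classify_interactions(pairs, self.regions) == ["none"]

    def test_labels_partition_and_are_idempotent(self):
        pairs = [
            (iv(100, 200), iv(4000, 4100)),
            (iv(100, 200), iv(100_100, 100_200)),
            (iv(50_000, 50_100), iv(60_000, 60_100)),
        ]
        first = classify_interactions(pairs, self.regions)
        assert classify_interactions(pairs, self.regions) == first
        assert set(first) <= {"self-interacting", "distant-interacting", "none"}


class TestShuffle:
    def test_lengths_preserved_as_multiset(self):
        regions = [iv(0, 4000), iv(10_000, 15_000), iv(20_000, 26_000)]
        shuffled = shuffle_regions(regions, {"chr1": 1_000_000}, seed=5)
        assert sorted(r.length for r in shuffled) == [4000, 5000, 6000]

    def test_seeded_determinism(self):
        regions = [iv(0, 4000)] * 3
        sizes = {"chr1": 1_000_000}
        assert shuffle_regions(regions, sizes, seed=9) == shuffle_regions(
            regions, sizes, seed=9
        )

    def test_outputs_mutually_disjoint(self):
        shuffled = shuffle_regions([iv(0, 3000)] * 30, {"chr1": 200_000}, seed=2)
        spans = sorted((r.start, r.end) for r in shuffled)
        assert all(s2 >= e1 for (_, e1), (s2, _) in zip(spans, spans[1:]))
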