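import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methconc.concurrence import (
    batch_region_concurrence,
    chalm,
    concurrence_ratio,
    concurrence_track,
    cpg_label_counts,
    dissect_read,
    mean_methylation,
    region_metrics,
)
from methconc.io import GenomicInterval

from conftest import make_read, make_reads


def labels(fragments):
    return [(f.label, f.weight) for f in fragments]


class TestDissect:
    def test_mixed_read_alternates_m_and_c(self):
        assert labels(dissect_read(make_read("1011"))) == [
            ("M", 1), ("C", 1), ("M", 2),
        ]

    def test_fully_unmethylated_is_single_u(self):
        assert labels(dissect_read(make_read("0000"))) == [("U", 4)]

    def test_fully_methylated_is_single_m(self):
        assert labels(dissect_read(make_read("111"))) == [("M", 3)]

    def test_missing_calls_bridge_runs(self):
        # the '?' between two methylated calls does not split the M run
        assert labels(dissect_read(make_read("1?10"))) == [("M", 2), ("C", 1)]

    def test_u_only_for_whole_reads(self):
        # unmethylated CpGs inside a mixed read are C, never U
        for pattern in ("01", "10", "010", "0011"):
            assert all(
                f.label in ("M", "C") for f in dissect_read(make_read(pattern))
            )

    def test_fragments_partition_observed_cpgs(self):
        rec = make_read("1?0110?01")
        frags = dissect_read(rec)
        covered = sorted(p for f in frags for p in f.positions)
        assert covered == [p for p, _ in rec.observed]


class TestConcurrenceRatio:
    def test_hand_enumerated_mixture(self, wide_region):
        # reads 1111, 0000, 1011 over 4 shared CpGs: one C label among 12
        reads = make_reads(["1111", "0000", "1011"])
        assert concurrence_ratio(reads, wide_region, coverage_min=3) == pytest.approx(
            1 / 12
        )

    def test_unweighted_counts_fragments_once(self, wide_region):
        # same mixture: fragments are M4, U1, (M1, C1, M2) -> 1 C of 5
        reads = make_reads(["1111", "0000", "1011"])
        assert concurrence_ratio(
            reads, wide_region, weighted=False, coverage_min=3
        ) == pytest.approx(1 / 5)

    @pytest.mark.parametrize("patterns", [["0000"] * 4, ["1111"] * 4])
    def test_concordant_reads_give_zero(self, patterns, wide_region):
        assert concurrence_ratio(make_reads(patterns), wide_region) == 0.0

    def test_no_qualifying_cpg_is_missing_not_zero(self, wide_region):
        reads = make_reads(["1010"] * 3)  # coverage 3 < 4
        assert concurrence_ratio(reads, wide_region, coverage_min=4) is None

    def test_labels_from_full_read_weights_from_region(self):
        # read 10: the M CpG lies outside the region, the C CpG inside.
        # The label C is kept (the read is partially methylated) even though
        # the region only sees the unmethylated CpG.
        reads = make_reads(["10"] * 4, start=100, spacing=10)
        region = GenomicInterval("chr1", 105, 200)
        assert concurrence_ratio(reads, region, coverage_min=4) == 1.0

    def test_single_read_bound(self):
        # exhaustive over all patterns of 1..6 CpGs: ratio < 1, max (k-1)/k
        region = GenomicInterval("chr1", 0, 1000)
        overall = 0.0
        for k in range(1, 7):
            best = 0.0
            for bits in itertools.product("01", repeat=k):
                r = concurrence_ratio(
                    [make_read("".join(bits))], region, coverage_min=1
                )
                best = max(best, r)
            assert best == pytest.approx((k - 1) / k)
            overall = max(overall, best)
        assert overall < 1.0


class TestPerCpGOracle:
    @staticmethod
    def oracle(reads, region, coverage_min):
        """Independent per-CpG count: a CpG observation is C-labeled iff its
        read is mixed and the call is 0; U/M otherwise."""
        cov = {}
        for rec in reads:
            for p, _ in rec.observed:
                cov[p] = cov.get(p, 0) + 1
        n_c = n_all = 0
        for rec in reads:
            calls = [c for _, c in rec.observed]
            mixed = 0 in calls and 1 in calls
            for p, c in rec.observed:
                if not (region.start <= p < region.end and cov[p] >= coverage_min):
                    continue
                n_all += 1
                if mixed and c == 0:
                    n_c += 1
        return None if n_all == 0 else n_c / n_all

    @given(
        st.lists(
            st.lists(st.sampled_from([0, 1, None]), min_size=1, max_size=8).filter(
                lambda c: any(x is not None for x in c)
            ),
            min_size=1,
            max_size=12,
        ),
        st.integers(min_value=1, max_value=4),
    )
    @settings(max_examples=200, deadline=None)
    def test_fragment_sum_equals_per_cpg_proportion(self, call_lists, cov_min):
        from methconc.io import EpireadRecord

        reads = [
            EpireadRecord(
                "chr1",
                f"r{i}",
                tuple(100 + 10 * j for j in range(len(calls))),
                tuple(calls),
            )
            for i, calls in enumerate(call_lists)
        ]
        region = GenomicInterval("chr1", 0, 1000)
        expect = self.oracle(reads, region, cov_min)
        got = concurrence_ratio(reads, region, coverage_min=cov_min)
        if expect is None:
            assert got is None
        else:
            assert got == pytest.approx(expect, abs=0)

    def test_batch_matches_per_region_computation(self):
        reads = make_reads(["1010", "0011", "1111", "0000", "1001"])
        regions = [
            GenomicInterval("chr1", 0, 115),
            GenomicInterval("chr1", 115, 1000),
            GenomicInterval("chr2", 0, 1000),
        ]
        batch = batch_region_concurrence(cpg_label_counts(reads), regions)
        single = [concurrence_ratio(reads, r) for r in regions]
        assert batch == single


class TestTracksAndRegionMetrics:
    def test_low_coverage_cpg_absent_from_track(self):
        reads = make_reads(["11", "11", "11"])  # coverage 3
        assert concurrence_track(reads, coverage_min=4) == {}

    def test_track_values_are_label_proportions(self):
        reads = make_reads(["10", "10", "10", "11"])
        track = concurrence_track(reads, coverage_min=4)["chr1"]
        assert track[100] == 0.0  # labels M,M,M,M at first CpG
        assert track[110] == 0.75  # C,C,C,M at second

    def test_mean_methylation(self, wide_region):
        assert mean_methylation(
            make_reads(["1111", "0000"]), wide_region, coverage_min=2
        ) == pytest.approx(0.5)
        assert mean_methylation(
            make_reads(["1011"] * 4), wide_region
        ) == pytest.approx(0.75)

    def test_mean_missing_without_cpgs(self):
        region = GenomicInterval("chr1", 5000, 6000)
        assert mean_methylation(make_reads(["11"] * 4), region) is None

    def test_chalm_counts_reads_with_any_methylation(self, wide_region):
        reads = make_reads(["1111", "0000", "1011"])
        assert chalm(reads, wide_region, coverage_min=3) == pytest.approx(2 / 3)
        assert chalm(make_reads(["0000"] * 4), wide_region) == 0.0
        assert chalm(make_reads(["0100", "1111", "0010", "1010"]), wide_region) == 1.0

    def test_chalm_equals_mean_for_single_cpg_reads(self, wide_region):
        reads = make_reads(["1", "0", "1", "1"])
        assert chalm(reads, wide_region) == mean_methylation(reads, wide_region)

    def test_strict_mode_drops_partially_covered_region(self, wide_region):
        # CpG at 120 only covered by 3 reads; others by 4
        reads = make_reads(["111", "111", "111", "11"])
        strict = region_metrics(reads, [wide_region], strict=True)[0]
        assert strict.mean_meth is None and strict.n_cpgs_used == 0
        lenient = region_metrics(reads, [wide_region], strict=False)[0]
        assert lenient.n_cpgs_used == 2  # the failing CpG alone is dropped
        assert lenient.mean_meth == 1.0

    def test_fully_covered_region_reported_in_strict_mode(self, wide_region):
        reads = make_reads(["10101", "01010", "11111", "00000"])
        m = region_metrics(reads, [wide_region], strict=True)[0]
        assert m.n_cpgs_used == 5 and m.n_reads_used == 4
        assert 0 <= m.concurrence_weighted < 1
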