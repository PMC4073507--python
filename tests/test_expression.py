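"""Count normalization, detection, CV, group comparisons, SNP densities and
mapping-table arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest

from lincpipe.expression import (
    coefficient_of_variation,
    compare_groups,
    detection_summary,
    mapping_summary,
    normalize_counts,
    snp_density,
)
from lincpipe.intervals import GenomicInterval, Locus

from conftest import make_transcript


def _matrix(counts, totals):
    samples = [f"S{i+1}" for i in range(len(totals))]
    raw = pd.DataFrame(
        counts, index=[f"g{i}" for i in range(len(counts))], columns=samples
    )
    return normalize_counts(raw, pd.Series(totals, index=samples))


class TestNormalize:
    def test_direct_ratio(self):
        m = _matrix([[10]], [1000])
        assert m.normalized.iloc[0, 0] == pytest.approx(0.01)

    def test_zero_count_row_stays_zero(self):
        m = _matrix([[0, 0, 0]], [10, 20, 30])
        assert (m.normalized.iloc[0] == 0).all()

    def test_round_trip_recovers_raw(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 1000, size=(30, 9))
        totals = rng.integers(10_000, 50_000, size=9)
        m = _matrix(counts, totals)
        back = m.normalized.mul(m.mapped_totals, axis=1)
        assert np.allclose(back.to_numpy(), counts)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            _matrix([[1, 2]], [100, 0])


class TestDetection:
    def test_counts_per_gene(self):
        m = _matrix([[1] * 9, [0] * 9, [5, 2, 0, 0, 0, 0, 0, 0, 0]], [10] * 9)
        detected, tallies = detection_summary(m)
        assert detected.tolist() == [9, 0, 2]
        assert tallies["detected_in_all"] == 1
        assert tallies["detected_in_fewer_than_5"] == 2

    def test_monotone_in_min_count(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng.integers(0, 5, size=(50, 9)), [100] * 9)
        prev = None
        for mc in (1, 2, 3, 4):
            detected, _ = detection_summary(m, min_count=mc)
            if prev is not None:
                assert (detected <= prev).all()
            prev = detected

    def test_planted_pattern_matches_generator_bookkeeping(self, default_bundle):
        from lincpipe.expression import normalize_counts as nc

        m = nc(default_bundle.counts, default_bundle.mapped_totals)
        detected, _ = detection_summary(m)
        for gid, kept in default_bundle.truth.low_detection.items():
            assert detected[gid] == kept


class TestCoefficientOfVariation:
    def test_constant_row_cv_zero(self):
        m = _matrix([[5, 5, 5]], [10, 10, 10])
        cv = coefficient_of_variation(m)
        assert cv.loc["g0", "cv_pct"] == pytest.approx(0.0)

    def test_two_point_formula(self):
        m = _matrix([[1, 3]], [1, 1])
        cv = coefficient_of_variation(m)
        assert cv.loc["g0", "cv_pct"] == pytest.approx(100 * math.sqrt(2) / 2)

    def test_zero_mean_flagged_not_dropped(self):
        m = _matrix([[0, 0], [1, 2]], [1, 1])
        cv = coefficient_of_variation(m)
        assert cv.loc["g0", "zero_mean"] and np.isnan(cv.loc["g0", "cv_pct"])
        assert not cv.loc["g1", "zero_mean"]

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 100, size=(20, 9))
        a = coefficient_of_variation(_matrix(counts, [1000] * 9))
        b = coefficient_of_variation(_matrix(counts * 7, [1000] * 9))
        assert np.allclose(a["cv_pct"], b["cv_pct"])

    def test_planted_dispersion_difference_orders_group_cvs(self, default_bundle):
        m = normalize_counts(default_bundle.counts, default_bundle.mapped_totals)
        cv = coefficient_of_variation(m)["cv_pct"]
        groups = default_bundle.truth.gene_group
        linc = [g for g, grp in groups.items() if grp == "linc"]
        coding = [g for g, grp in groups.items() if grp == "coding"]
        assert cv[linc].mean() > cv[coding].mean()


class TestCompareGroups:
    def test_identical_groups_give_null_result(self):
        res = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_textbook_pooled_t(self):
        a, b = [1.0, 2.0], [3.0, 5.0]
        res = compare_groups(a, b)
        # hand pooled-t: means 1.5/4.0, s2p = (0.5 + 2)/2 = 1.25
        want = (1.5 - 4.0) / math.sqrt(1.25 * (0.5 + 0.5))
        assert res.statistic == pytest.approx(want)
        assert res.format_means() == "1.50 +/- 0.71 versus 4.00 +/- 1.41"

    def test_power_under_three_sd_shift(self):
        rejected = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, 100)
            b = rng.normal(3, 1, 100)
            if compare_groups(a, b).p_value < 1e-3:
                rejected += 1
        assert rejected >= 50 * 0.99


class TestSnpDensity:
    def test_uniform_snps_in_upstream_window(self):
        locus = Locus("L1", frozenset({"t"}), GenomicInterval("chr1", 50_000, 52_000, "+"))
        snps = pd.DataFrame(
            {"chrom": "chr1", "pos": np.linspace(40_000, 49_999, 10, dtype=int)}
        )
        dens = snp_density([locus], snps)
        assert dens.loc["L1", "upstream_density"] == pytest.approx(1.0)
        assert dens.loc["L1", "downstream_density"] == pytest.approx(0.0)

    def test_minus_strand_reflects_windows(self):
        locus = Locus("L1", frozenset({"t"}), GenomicInterval("chr1", 50_000, 52_000, "-"))
        snps = pd.DataFrame({"chrom": "chr1", "pos": [52_500, 61_000, 49_500]})
        dens = snp_density([locus], snps)
        # upstream lies on the higher-coordinate side for minus-strand loci
        assert dens.loc["L1", "upstream_density"] == pytest.approx(2 / 10.0)
        assert dens.loc["L1", "downstream_density"] == pytest.approx(1 / 1.0)

    def test_counts_match_bruteforce_scan(self):
        rng = np.random.default_rng(21)
        snps = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], 2000),
                "pos": rng.integers(0, 1_000_000, 2000),
            }
        )
        loci = []
        for i in range(50):
            start = int(rng.integers(20_000, 900_000))
            strand = "+" if rng.random() < 0.5 else "-"
            chrom = ["chr1", "chr2"][int(rng.integers(0, 2))]
            loci.append(
                Locus(f"L{i}", frozenset({"t"}), GenomicInterval(chrom, start, start + 3000, strand))
            )
        dens = snp_density(loci, snps)
        for locus in loci:
            s = locus.span
            if s.strand == "-":
                up = (s.end, s.end + 10_000)
                down = (s.start - 1_000, s.start)
            else:
                up = (s.start - 10_000, s.start)
                down = (s.end, s.end + 1_000)
            for window, col, kb in ((up, "upstream_density", 10.0), (down, "downstream_density", 1.0)):
                count = sum(
                    1
                    for c, p in zip(snps["chrom"], snps["pos"])
                    if c == s.chrom and window[0] <= p < window[1]
                )
                assert dens.loc[locus.locus_id, col] == pytest.approx(count / kb)

    def test_conservation_of_counts(self):
        # windows cannot count more SNPs than exist
        rng = np.random.default_rng(22)
        snps = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(0, 100_000, 100)})
        loci = [
            Locus(f"L{i}", frozenset({"t"}), GenomicInterval("chr1", 30_000 + 25_000 * i, 31_000 + 25_000 * i, "+"))
            for i in range(3)
        ]
        dens = snp_density(loci, snps)
        total = (dens["upstream_density"] * 10 + dens["downstream_density"] * 1).sum()
        assert total <= 100


class TestMappingSummary:
    def test_fully_mapped_sample(self):
        ms = mapping_summary(
            {"s": {"n_reads": 1000, "n_mapped": 1000, "n_uniquely_mapped": 900}}
        )
        assert ms.per_sample.loc["s", "pct_mapped"] == 100.00
        assert ms.per_sample.loc["s", "pct_uniquely_mapped"] == 90.00

    def test_half_up_rounding(self):
        ms = mapping_summary(
            {"s": {"n_reads": 80_000, "n_mapped": 60_404, "n_uniquely_mapped": 100}}
        )
        # 75.505 rounds half-up to 75.51
        assert ms.per_sample.loc["s", "pct_mapped"] == 75.51

    def test_invariant_violation_rejected(self):
        with pytest.raises(ValueError):
            mapping_summary(
                {"s": {"n_reads": 100, "n_mapped": 150, "n_uniquely_mapped": 10}}
            )
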