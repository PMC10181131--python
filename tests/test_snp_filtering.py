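"""Cohort-VCF filters: quality, density windows, perfect-SNP selection."""

import itertools
import math

import numpy as np
import pytest

from tetrafinger.io_formats import VariantRecord, read_vcf
from tetrafinger.snp_filtering import (filter_high_quality,
                                       partition_biallelic,
                                       select_perfect_snps, site_qc,
                                       snp_density, snp_rich_regions)


def _site(chrom="chr01", pos=100, n_alt=1, genotypes=None, depths=None):
    return VariantRecord(chrom, pos, "A", tuple("GCT"[:n_alt]),
                         genotypes=genotypes or [], depths=depths or [])


def _make_site(pos, dosages, depth_per_sample=10, chrom="chr01"):
    """Biallelic site from a list of dosages (None = missing call)."""
    gts, ads = [], []
    for d in dosages:
        if d is None:
            gts.append(None)
            ads.append((0, 0))
        else:
            gts.append(tuple([1] * d + [0] * (4 - d)))
            n_alt = round(depth_per_sample * d / 4)
            ads.append((depth_per_sample - n_alt, n_alt))
    return VariantRecord(chrom, pos, "A", ("G",), genotypes=gts, depths=ads)


class TestPartition:
    def test_all_single_alt(self):
        sites = [_site(pos=p) for p in (1, 2, 3)]
        bi, multi = partition_biallelic(sites)
        assert len(bi) == 3 and multi == []

    def test_known_split_preserves_order(self):
        sites = [_site(pos=p, n_alt=2 if p % 4 == 0 else 1)
                 for p in range(1, 11)]
        bi, multi = partition_biallelic(sites)
        assert (len(bi), len(multi)) == (8, 2)
        assert [v.pos for v in bi] == sorted(v.pos for v in bi)

    def test_empty(self):
        assert partition_biallelic([]) == ([], [])


class TestHighQualityFilter:
    def test_integrity_boundary_is_strict(self):
        # 17/20 called = 0.85 exactly -> removed
        dosages = [2] * 17 + [None] * 3
        site = _make_site(100, dosages)
        kept, _ = filter_high_quality([site], 20)
        assert kept == []

    def test_passing_site_kept(self):
        # integrity 0.9, minor reads 4 > 3
        site = _make_site(100, [0] * 14 + [1] * 4 + [None] * 2,
                          depth_per_sample=4)
        qc = site_qc(site, 20)
        assert qc.minor_allele_reads == 4
        kept, _ = filter_high_quality([site], 20)
        assert kept == [site]

    def test_minor_reads_boundary_is_strict(self):
        site = _make_site(100, [0] * 15 + [1] * 3 + [None] * 2,
                          depth_per_sample=4)
        assert site_qc(site, 20).minor_allele_reads == 3
        kept, _ = filter_high_quality([site], 20)
        assert kept == []

    def test_missing_ad_raises_unless_disabled(self):
        site = VariantRecord("chr01", 5, "A", ("G",),
                             genotypes=[(0, 0, 1, 1)], depths=[None])
        with pytest.raises(ValueError, match="use_read_support"):
            filter_high_quality([site], 1)
        kept, _ = filter_high_quality([site], 1, use_read_support=False)
        assert kept == [site]

    def test_low_depth_cohort_matches_brute_force(self, tmp_path):
        """Survivors at mean depth 1 equal a site-by-site re-application
        of both criteria."""
        from tetrafinger.synthetic_data import simulate_cohort_vcf
        vcf, _, _ = simulate_cohort_vcf(30, 30, 3, 2, mean_depth=1.0,
                                        seed=77, out_dir=tmp_path)
        cohort = read_vcf(vcf)
        kept, qcs = filter_high_quality(cohort.records, len(cohort.samples))
        expected = []
        for rec in cohort.records:
            if len(rec.alts) != 1:
                continue
            called = [g for g in rec.genotypes if g is not None]
            integrity = len(called) / len(cohort.samples)
            counts = [0, 0]
            for g in called:
                for a in g:
                    counts[min(a, 1)] += 1
            minor = 0 if counts[0] < counts[1] else 1
            reads = sum(ad[minor] for ad in rec.depths if ad is not None)
            if integrity > 0.85 and reads > 3:
                expected.append(rec.key)
        assert [v.key for v in kept] == expected
        assert len(kept) < len(cohort.records)  # depth 1 kills most sites


class TestDensity:
    def test_first_position_lands_in_first_bin(self):
        windows = snp_density([_site(pos=1)], {"chr01": 3_000_000})
        assert [w.snp_count for w in windows] == [1, 0, 0]

    def test_uniform_counts(self):
        sites = [_site(pos=p) for p in range(500, 1_000_000, 10_000)]
        windows = snp_density(sites, {"chr01": 1_000_000}, bin=100_000)
        assert all(w.snp_count == 10 for w in windows)

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(13)
        positions = sorted(rng.integers(1, 500_001, size=300).tolist())
        sites = [_site(pos=int(p)) for p in positions]
        windows = snp_density(sites, {"chr01": 500_000}, bin=50_000)
        for w in windows:
            expected = sum(1 for p in positions if w.start < p <= w.end)
            assert w.snp_count == expected
        assert sum(w.snp_count for w in windows) == 300

    def test_unknown_contig_rejected(self):
        with pytest.raises(ValueError, match="unknown contig"):
            snp_density([_site(chrom="chrX")], {"chr01": 100})

    def test_partial_last_window_kept(self):
        windows = snp_density([], {"chr01": 150_000}, bin=100_000)
        assert (windows[-1].start, windows[-1].end) == (100_000, 150_000)


class TestRichRegions:
    def test_all_tied_all_flagged(self):
        sites = [_site(pos=p) for p in (50, 150, 250, 350)]
        windows = snp_rich_regions(sites, {"chr01": 400}, window=100,
                                   top_frac=0.25)
        assert all(w.rich for w in windows)

    def test_planted_hotspot(self):
        background = [_site(pos=p) for p in range(1000, 100_000, 5000)]
        hotspot = [_site(pos=p) for p in range(50_001, 50_100, 10)]
        windows = snp_rich_regions(background + hotspot, {"chr01": 100_000},
                                   window=1000, top_frac=0.01)
        rich = [w for w in windows if w.rich]
        assert len(rich) == 1
        assert rich[0].start == 50_000

    def test_zero_variants_nothing_flagged(self):
        windows = snp_rich_regions([], {"chr01": 1_000_000})
        assert not any(w.rich for w in windows)


class TestPerfectSnps:
    def _good_site(self, pos, chrom="chr01"):
        # 7 nulliplex, 3 duplex, 7 quadruplex, 3 missing: MAF ~0.5,
        # miss 0.15, het 3/17 ~ 0.18
        return _make_site(pos, [0] * 7 + [2] * 3 + [4] * 7 + [None] * 3,
                          chrom=chrom)

    def test_mutual_flank_exclusion(self):
        a, b = self._good_site(1000), self._good_site(1050)
        selected, report = select_perfect_snps([a, b], 20)
        assert selected == []
        assert report[a.key] == ["flanking_variant"]
        assert report[b.key] == ["flanking_variant"]

    def test_flank_boundary_inclusive(self):
        a, b = self._good_site(1000), self._good_site(1100)
        selected, _ = select_perfect_snps([a, b], 20)
        assert selected == []  # exactly 100 bp apart -> excluded
        c, d = self._good_site(2000), self._good_site(2101)
        selected, _ = select_perfect_snps([c, d], 20)
        assert {v.pos for v in selected} == {2000, 2101}

    def test_maf_boundary_is_strict(self):
        # allele-B copies 32 of 80 -> MAF exactly 0.4
        site = _make_site(500, [0] * 12 + [4] * 8)
        qc = site_qc(site, 20)
        assert qc.maf == pytest.approx(0.4)
        selected, report = select_perfect_snps([site], 20)
        assert selected == []
        assert "maf" in report[site.key]

    def test_recovers_planted_truth(self, cohort_fixture):
        vcf, _, truth = cohort_fixture
        cohort = read_vcf(vcf)
        selected, report = select_perfect_snps(cohort.records,
                                               len(cohort.samples))
        assert {v.key for v in selected} == truth.perfect_ids
        for key in truth.flank_violator_ids:
            assert report[key] == ["flanking_variant"]

    def test_every_rejected_site_reported(self, cohort_fixture):
        vcf, _, _ = cohort_fixture
        cohort = read_vcf(vcf)
        selected, report = select_perfect_snps(cohort.records,
                                               len(cohort.samples))
        rejected = {r.key for r in cohort.records} - {v.key for v in selected}
        assert set(report) == rejected
        assert all(len(v) >= 1 for v in report.values())

    def test_criteria_order_insensitive(self, cohort_fixture):
        """Filter composition gives the same survivors in any order."""
        vcf, _, _ = cohort_fixture
        cohort = read_vcf(vcf)
        n = len(cohort.samples)

        def by_maf(recs):
            return [r for r in recs if site_qc(r, n).maf > 0.4]

        def by_miss(recs):
            return [r for r in recs if site_qc(r, n).miss_rate < 0.2]

        def by_het(recs):
            return [r for r in recs if site_qc(r, n).het_fraction < 0.4]

        def by_flank(recs):
            kept, _ = select_perfect_snps(
                recs, n, maf_min=0, miss_max=1.01, het_max=1.01,
                universe=cohort.records)
            return kept

        results = set()
        for order in itertools.permutations([by_maf, by_miss, by_het,
                                             by_flank]):
            recs = list(cohort.records)
            for f in order:
                recs = f(recs)
            results.add(tuple(r.key for r in recs))
        assert len(results) == 1
        joint, _ = select_perfect_snps(cohort.records, n)
        assert results.pop() == tuple(r.key for r in joint)
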