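"""Cohort-VCF marker discovery: quality filters, density windows and
perfect-SNP selection.

The discovery stage mirrors a reduced-representation genotyping workflow
on an autotetraploid cohort: sites are first screened for cohort-level
quality (minor-allele read support and call integrity), SNP density is
profiled in fixed bins, density hotspots are flagged, and finally
"perfect SNP" candidates — biallelic sites suitable for conversion to an
allele-specific PCR assay — are selected on minor-allele frequency,
missingness, heterozygosity and flanking-variant criteria.  All
thresholds are strict inequalities.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass

from .io_formats import VariantCohort, VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class SiteQC:
    """Cohort-level quality metrics for one variant site."""

    key: str
    n_samples: int
    n_called: int
    minor_allele_reads: int | None
    maf: float
    het_fraction: float

    @property
    def integrity(self) -> float:
        return self.n_called / self.n_samples if self.n_samples else math.nan

    @property
    def miss_rate(self) -> float:
        return 1.0 - self.integrity


@dataclass
class WindowCount:
    """SNP tally for one genomic window (0-based half-open)."""

    chrom: str
    start: int
    end: int
    snp_count: int
    rich: bool = False


def partition_biallelic(
        variants: list[VariantRecord],
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split sites into biallelic (exactly one ALT) and multiallelic,
    preserving input order."""
    biallelic = [v for v in variants if len(v.alts) == 1]
    multi = [v for v in variants if len(v.alts) != 1]
    logger.info("partitioned %d sites: %d biallelic, %d multiallelic",
                len(variants), len(biallelic), len(multi))
    return biallelic, multi


def site_qc(record: VariantRecord, n_samples: int) -> SiteQC:
    """Compute integrity, MAF, heterozygous fraction and cohort-wide
    minor-allele read support for one biallelic site.

    Allele frequency counts each sample's allele copies from its genotype
    (ploidy 2 or 4); the minor allele is the less frequent of REF/ALT
    (ties resolved to ALT).  Read support sums the per-sample AD entry of
    the minor allele over all samples; it is None when AD is absent.
    """
    allele_counts = [0, 0]
    n_called = 0
    n_het = 0
    for gt in record.genotypes:
        if gt is None:
            continue
        n_called += 1
        for a in gt:
            allele_counts[min(a, 1)] += 1
        if len(set(gt)) > 1:
            n_het += 1
    total = sum(allele_counts)
    if total == 0:
        maf = 0.0
        minor_idx = 1
    else:
        minor_idx = 0 if allele_counts[0] < allele_counts[1] else 1
        maf = allele_counts[minor_idx] / total
    if record.has_depths:
        minor_reads = sum(ad[minor_idx] for ad in record.depths
                          if ad is not None and len(ad) > minor_idx)
    else:
        minor_reads = None
    return SiteQC(key=record.key, n_samples=n_samples, n_called=n_called,
                  minor_allele_reads=minor_reads, maf=maf,
                  het_fraction=n_het / n_called if n_called else 0.0)


def filter_high_quality(
        variants: list[VariantRecord],
        n_samples: int,
        min_minor_reads: int = 3,
        min_integrity: float = 0.85,
        use_read_support: bool = True,
) -> tuple[list[VariantRecord], list[SiteQC]]:
    """High-quality site filter: biallelic sites with cohort-wide
    minor-allele read support > ``min_minor_reads`` and call integrity
    > ``min_integrity`` (both strict).

    Returns the surviving records plus a :class:`SiteQC` per input
    biallelic site for audit.  Raises if AD data are absent unless the
    read-support criterion is explicitly disabled.
    """
    biallelic, _ = partition_biallelic(variants)
    qcs = [site_qc(v, n_samples) for v in biallelic]
    if use_read_support and any(q.minor_allele_reads is None for q in qcs):
        raise ValueError(
            "allele-depth (AD) data missing for some sites; pass "
            "use_read_support=False to filter on integrity alone")
    kept = []
    for v, q in zip(biallelic, qcs):
        if q.integrity <= min_integrity:
            continue
        if use_read_support and not q.minor_allele_reads > min_minor_reads:
            continue
        kept.append(v)
    logger.info("high-quality filter: %d of %d biallelic sites kept",
                len(kept), len(biallelic))
    return kept, qcs


def _tile_windows(contig_lengths: dict[str, int], size: int) -> list[WindowCount]:
    windows = []
    for chrom in contig_lengths:
        length = contig_lengths[chrom]
        start = 0
        while start < length:
            windows.append(WindowCount(chrom, start, min(start + size, length), 0))
            start += size
    return windows


def snp_density(variants: list[VariantRecord],
                contig_lengths: dict[str, int],
                bin: int = 1_000_000) -> list[WindowCount]:
    """Count SNPs per non-overlapping bin along every contig.

    Windows are 0-based half-open; the last partial window of a contig is
    kept.  A variant on a contig absent from ``contig_lengths`` is an
    error.
    """
    windows = _tile_windows(contig_lengths, bin)
    index = {}
    for w in windows:
        index.setdefault(w.chrom, []).append(w)
    for v in variants:
        if v.chrom not in index:
            raise ValueError(f"variant {v.key} on unknown contig {v.chrom!r}")
        if v.pos > contig_lengths[v.chrom]:
            raise ValueError(f"variant {v.key} beyond contig end")
        index[v.chrom][(v.pos - 1) // bin].snp_count += 1
    return windows


def snp_rich_regions(variants: list[VariantRecord],
                     contig_lengths: dict[str, int],
                     window: int = 100_000,
                     top_frac: float = 0.01) -> list[WindowCount]:
    """Flag the top-fraction highest-SNP-count windows as SNP-rich.

    The cutoff rank is ``ceil(top_frac * n_windows)`` over all contigs
    jointly; all windows tied with the cutoff count are flagged (and the
    tie logged).  With zero variants nothing is flagged.
    """
    windows = snp_density(variants, contig_lengths, bin=window)
    if not variants or not windows:
        return windows
    n_top = math.ceil(top_frac * len(windows))
    counts = sorted((w.snp_count for w in windows), reverse=True)
    cutoff = counts[n_top - 1]
    if cutoff == 0:
        # top-ranked windows are empty; nothing qualifies as rich
        return windows
    flagged = 0
    for w in windows:
        if w.snp_count >= cutoff:
            w.rich = True
            flagged += 1
    if flagged > n_top:
        logger.warning("tie at SNP-rich cutoff (count=%d): flagged %d windows "
                       "for a nominal top of %d", cutoff, flagged, n_top)
    return windows


def select_perfect_snps(
        variants: list[VariantRecord],
        n_samples: int,
        maf_min: float = 0.4,
        miss_max: float = 0.2,
        het_max: float = 0.4,
        flank_bp: int = 100,
        universe: list[VariantRecord] | None = None,
) -> tuple[list[VariantRecord], dict[str, list[str]]]:
    """Select perfect-SNP candidates and report failed criteria per site.

    A biallelic site qualifies when (all strict): MAF > ``maf_min``,
    miss rate < ``miss_max``, heterozygous-sample fraction < ``het_max``,
    and no other variant lies within ``flank_bp`` bp (inclusive) on the
    same contig.  ``universe`` is the variant catalogue used for the
    flanking criterion; it defaults to ``variants`` and would normally be
    the full cohort VCF.

    Returns the candidates plus a mapping from rejected-site key to the
    list of failed criterion names.
    """
    universe = variants if universe is None else universe
    positions: dict[str, list[int]] = {}
    for v in universe:
        positions.setdefault(v.chrom, []).append(v.pos)
    for chrom in positions:
        positions[chrom].sort()

    def has_flanking(v: VariantRecord) -> bool:
        pos = positions.get(v.chrom, [])
        lo = bisect_left(pos, v.pos - flank_bp)
        hi = bisect_right(pos, v.pos + flank_bp)
        # the window [pos-flank, pos+flank] may contain the site itself
        n_self = sum(1 for p in pos[lo:hi] if p == v.pos)
        return (hi - lo - n_self) > 0 or n_self > 1

    selected = []
    report: dict[str, list[str]] = {}
    for v in variants:
        failed = []
        if v.is_multiallelic:
            failed.append("multiallelic")
            qc = None
        else:
            qc = site_qc(v, n_samples)
            if not qc.maf > maf_min:
                failed.append("maf")
            if not qc.miss_rate < miss_max:
                failed.append("miss_rate")
            if not qc.het_fraction < het_max:
                failed.append("heterozygosity")
        if has_flanking(v):
            failed.append("flanking_variant")
        if failed:
            report[v.key] = failed
        else:
            selected.append(v)
    logger.info("perfect-SNP selection: %d of %d sites selected",
                len(selected), len(variants))
    return selected, report
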