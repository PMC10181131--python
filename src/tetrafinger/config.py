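"""Run configuration shared by every pipeline stage.

All thresholds default to the values used in the potato PARMS-SNP study
workflow this package implements: cohort SNP quality filtering
(minor-allele read support > 3, call integrity > 85%), perfect-SNP
selection (MAF > 0.4, miss rate < 0.2, heterozygous fraction < 0.4,
no other variant within 100 bp), mixture-model dosage calling
(posterior threshold 0.6, peak threshold 1.0), and fingerprint locus
selection (PIC > 0.6).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    """Thresholds and window sizes for a full pipeline run.

    Parameters
    ----------
    min_minor_reads : int
        Cohort-wide read support required for the minor allele at a site
        (strictly greater-than) in the high-quality filter.
    min_integrity : float
        Fraction of samples that must carry a genotype call at a site
        (strictly greater-than).
    maf_min, miss_max, het_max : float
        Perfect-SNP criteria: minor-allele frequency strictly above
        ``maf_min``, missing-call rate strictly below ``miss_max``,
        heterozygous-sample fraction strictly below ``het_max``.
    flank_bp : int
        Exclusion radius in bp: a perfect-SNP candidate may have no other
        variant within this distance (inclusive) on the same contig.
    pic_threshold : float
        Markers with PIC strictly above this enter the fingerprint.
    posterior_threshold : float
        Minimum mixture posterior for a dosage call to be assigned.
    peak_threshold : float
        If the largest mixture component holds a sample fraction strictly
        above this, the marker is flagged non-segregating. The default of
        1.0 disables the flag.
    density_bin : int
        Bin size in bp for SNP density profiles.
    rich_window : int
        Window size in bp for SNP-rich-region scans.
    rich_top_frac : float
        Fraction of highest-count windows flagged SNP-rich.
    rng_seed : int
        Seed for every stochastic stage (EM restarts, simulators).
    """

    min_minor_reads: int = 3
    min_integrity: float = 0.85
    maf_min: float = 0.4
    miss_max: float = 0.2
    het_max: float = 0.4
    flank_bp: int = 100
    pic_threshold: float = 0.6
    posterior_threshold: float = 0.6
    peak_threshold: float = 1.0
    density_bin: int = 1_000_000
    rich_window: int = 100_000
    rich_top_frac: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_integrity", "maf_min", "miss_max", "het_max",
                     "pic_threshold", "posterior_threshold", "rich_top_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.peak_threshold <= 1.0:
            raise ValueError("peak_threshold must lie in [0, 1]")
        for name in ("flank_bp", "density_bin", "rich_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_minor_reads < 0:
            raise ValueError("min_minor_reads must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")
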