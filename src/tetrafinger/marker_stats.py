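"""Per-marker dosage statistics for tetraploid SNP panels.

For each marker the samples fall into five dosage classes by allele-B
copy number: 0 (AAAA), 1 (AAAB), 2 (AABB), 3 (ABBB), 4 (BBBB).  From the
class tally ``n0..n4`` over called samples (``n_called = sum``):

* ``MA``  — mean A-allele frequency: ``sum_d (4-d)*n_d / (4*n_called)``;
* ``OH``  — observed heterozygosity: ``(n1+n2+n3)/n_called``;
* ``PIC`` — polymorphic information content as used for tetraploid
  dosage panels: gene diversity over the five genotype classes,
  ``1 - sum_g f_g**2`` with ``f_g = n_g/n_called``.  Its maximum is 0.8
  (five equal classes); it is 0 iff a single class is observed.

Missing calls are excluded from every denominator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DOSAGE_CLASSES = (0, 1, 2, 3, 4)


@dataclass
class MarkerStatsRecord:
    """Dosage-class tally plus MA, OH and PIC for one marker."""

    marker: str
    counts: tuple[int, int, int, int, int]
    n_missing: int
    ma: float
    oh: float
    pic: float

    @property
    def n_called(self) -> int:
        return sum(self.counts)

    @property
    def n_classes(self) -> int:
        return sum(1 for c in self.counts if c > 0)


def tally_dosages(column) -> tuple[tuple[int, int, int, int, int], int]:
    """Tally a dosage column into class counts (n0..n4) and a missing count.

    Accepts any iterable of values in {0..4} or NaN/None for missing.
    """
    counts = [0] * 5
    n_missing = 0
    for v in column:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            n_missing += 1
            continue
        d = int(v)
        if d != v or not 0 <= d <= 4:
            raise ValueError(f"dosage value {v!r} outside 0..4")
        counts[d] += 1
    return tuple(counts), n_missing


def mean_A_frequency(counts) -> float:
    """MA: fraction of A-allele copies among all called allele copies.

    With dosage d = number of B copies, each called sample contributes
    ``4 - d`` A copies out of 4.
    """
    n_called = sum(counts)
    if n_called == 0:
        return math.nan
    a_copies = sum((4 - d) * n for d, n in zip(DOSAGE_CLASSES, counts))
    return a_copies / (4 * n_called)


def observed_heterozygosity(counts) -> float:
    """OH: fraction of called samples with a mixed genotype (dosage 1-3)."""
    n_called = sum(counts)
    if n_called == 0:
        return math.nan
    return (counts[1] + counts[2] + counts[3]) / n_called


def pic(counts) -> float:
    """PIC: 1 minus the sum of squared dosage-class frequencies."""
    n_called = sum(counts)
    if n_called == 0:
        return math.nan
    return 1.0 - sum((n / n_called) ** 2 for n in counts)


def stats_from_counts(counts_df: pd.DataFrame) -> pd.DataFrame:
    """Compute the per-marker statistics table from class counts.

    ``counts_df`` must carry columns ``n0..n4`` and ``n_missing``, indexed
    by marker name, as produced by tallying or loaded from a published
    table.  Returns a DataFrame with the tally plus n_called, MA, OH, PIC.
    """
    rows = []
    for marker, row in counts_df.iterrows():
        counts = tuple(int(row[f"n{d}"]) for d in DOSAGE_CLASSES)
        rows.append({
            "marker": marker,
            **{f"n{d}": counts[d] for d in DOSAGE_CLASSES},
            "n_missing": int(row["n_missing"]),
            "n_called": sum(counts),
            "MA": mean_A_frequency(counts),
            "OH": observed_heterozygosity(counts),
            "PIC": pic(counts),
        })
    return pd.DataFrame(rows).set_index("marker")


def compute_marker_stats(matrix: pd.DataFrame) -> pd.DataFrame:
    """Tally a samples x markers dosage matrix and compute MA/OH/PIC."""
    counts_rows = []
    for marker in matrix.columns:
        counts, n_missing = tally_dosages(matrix[marker])
        counts_rows.append({"marker": marker,
                            **{f"n{d}": counts[d] for d in DOSAGE_CLASSES},
                            "n_missing": n_missing})
    counts_df = pd.DataFrame(counts_rows).set_index("marker")
    return stats_from_counts(counts_df)


def n_dosage_classes(stats: pd.DataFrame) -> pd.Series:
    count_cols = [f"n{d}" for d in DOSAGE_CLASSES]
    return (stats[count_cols] > 0).sum(axis=1)


def summarize_markers(stats: pd.DataFrame) -> dict:
    """Cohort-level summary of a marker-statistics table.

    Returns min/mean/max of MA, OH and PIC (computed on the unrounded
    per-marker values), the number of markers with a single observed
    dosage class, and the number with MA > 0.5.
    """
    if len(stats) == 0:
        raise ValueError("cannot summarise an empty statistics table")
    classes = n_dosage_classes(stats)
    out: dict = {"n_markers": int(len(stats))}
    for col in ("MA", "OH", "PIC"):
        vals = stats[col].dropna()
        out[col] = {"min": float(vals.min()), "mean": float(vals.mean()),
                    "max": float(vals.max())}
    out["n_single_class"] = int((classes == 1).sum())
    out["n_ma_above_half"] = int((stats["MA"] > 0.5).sum())
    out["class_count_distribution"] = {
        int(k): int(v) for k, v in classes.value_counts().sort_index().items()}
    return out


def drop_monomorphic(matrix: pd.DataFrame,
                     stats: pd.DataFrame) -> pd.DataFrame:
    """Remove markers showing exactly one dosage class, preserving order.

    Monomorphic markers carry no information for distances, fingerprints
    or diversity analysis.
    """
    classes = n_dosage_classes(stats)
    keep = [m for m in matrix.columns if classes.get(m, 0) != 1]
    dropped = [m for m in matrix.columns if m not in keep]
    if dropped:
        logger.info("dropped %d monomorphic markers: %s", len(dropped), dropped)
    if not keep:
        logger.warning("all markers monomorphic; returning empty matrix")
    return matrix[keep]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching how published tables print."""
    if math.isnan(x):
        return x
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
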