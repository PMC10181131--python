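"""Published reference panel: the 71-marker potato PARMS-SNP dosage-class table.

Each row gives, for one SNP marker assayed on a panel of autotetraploid
potato varieties, the number of samples called in each allele-B dosage
class (0 = AAAA nulliplex ... 4 = BBBB quadruplex), the number of samples
with no call, and the observed heterozygosity (OH), mean A-allele
frequency (MA) and polymorphic information content (PIC) as printed in
the source publication.  The printed statistics are retained only for
cross-checking; pipeline code recomputes everything from the counts.
"""

from __future__ import annotations

import pandas as pd

# marker, n0, n1, n2, n3, n4, n_missing, printed OH, printed MA, printed PIC
PARMS_SNP_PANEL: tuple[tuple, ...] = (
    ("StSNP54", 4, 11, 52, 71, 39, 15, 0.76, 0.32, 0.7),
    ("StSNP57", 78, 46, 43, 18, 0, 7, 0.58, 0.75, 0.7),
    ("StSNP41", 0, 15, 36, 69, 60, 12, 0.67, 0.26, 0.7),
    ("StSNP24", 13, 64, 77, 29, 7, 2, 0.89, 0.56, 0.69),
    ("StSNP11", 11, 65, 78, 30, 6, 2, 0.91, 0.56, 0.69),
    ("StSNP96", 32, 88, 41, 23, 0, 8, 0.83, 0.68, 0.68),
    ("StSNP78", 70, 70, 28, 14, 0, 10, 0.62, 0.77, 0.67),
    ("StSNP86", 72, 42, 66, 1, 0, 11, 0.6, 0.76, 0.65),
    ("StSNP87", 74, 70, 39, 2, 0, 7, 0.6, 0.79, 0.65),
    ("StSNP8", 48, 85, 38, 5, 0, 16, 0.73, 0.75, 0.64),
    ("StSNP115", 64, 83, 25, 5, 3, 12, 0.63, 0.78, 0.64),
    ("StSNP19", 0, 0, 41, 62, 85, 4, 0.55, 0.19, 0.64),
    ("StSNP148", 23, 23, 90, 31, 0, 25, 0.86, 0.56, 0.64),
    ("StSNP16", 75, 77, 34, 0, 0, 6, 0.6, 0.81, 0.63),
    ("StSNP127", 0, 3, 27, 75, 74, 12, 0.59, 0.19, 0.63),
    ("StSNP38", 91, 62, 29, 5, 0, 5, 0.51, 0.82, 0.63),
    ("StSNP83", 32, 84, 71, 0, 0, 5, 0.83, 0.7, 0.62),
    ("StSNP70", 35, 93, 62, 0, 0, 2, 0.82, 0.71, 0.62),
    ("StSNP13", 70, 76, 17, 6, 1, 3, 0.58, 0.81, 0.62),
    ("StSNP119", 67, 89, 31, 0, 0, 5, 0.64, 0.8, 0.62),
    ("StSNP133", 0, 1, 24, 69, 85, 13, 0.53, 0.17, 0.61),
    ("StSNP80", 78, 89, 23, 0, 0, 2, 0.59, 0.82, 0.6),
    ("StSNP39", 39, 104, 46, 0, 0, 3, 0.79, 0.74, 0.6),
    ("StSNP21", 71, 94, 22, 0, 0, 5, 0.62, 0.82, 0.59),
    ("StSNP30", 64, 97, 20, 1, 0, 9, 0.65, 0.81, 0.58),
    ("StSNP26", 40, 109, 39, 1, 0, 3, 0.79, 0.75, 0.58),
    ("StSNP33", 83, 82, 16, 0, 0, 11, 0.54, 0.84, 0.58),
    ("StSNP109", 58, 101, 20, 0, 0, 13, 0.68, 0.8, 0.56),
    ("StSNP106", 61, 103, 17, 1, 0, 10, 0.66, 0.81, 0.56),
    ("StSNP112", 102, 67, 13, 2, 0, 8, 0.45, 0.87, 0.55),
    ("StSNP76", 19, 109, 60, 0, 0, 4, 0.9, 0.7, 0.55),
    ("StSNP104", 61, 105, 15, 0, 0, 11, 0.66, 0.81, 0.54),
    ("StSNP90", 114, 51, 20, 2, 0, 4, 0.39, 0.87, 0.54),
    ("StSNP110", 115, 47, 13, 9, 0, 8, 0.38, 0.86, 0.54),
    ("StSNP141", 34, 114, 32, 0, 0, 12, 0.81, 0.75, 0.53),
    ("StSNP99", 0, 2, 6, 66, 96, 22, 0.44, 0.12, 0.53),
    ("StSNP7", 26, 118, 34, 0, 0, 14, 0.85, 0.74, 0.5),
    ("StSNP93", 25, 117, 34, 0, 0, 16, 0.86, 0.74, 0.5),
    ("StSNP84", 0, 4, 14, 118, 35, 20, 0.8, 0.23, 0.47),
    ("StSNP47", 130, 42, 7, 5, 0, 8, 0.29, 0.9, 0.45),
    ("StSNP72", 0, 55, 126, 0, 0, 11, 1.0, 0.58, 0.42),
    ("StSNP92", 2, 131, 31, 14, 0, 14, 0.99, 0.67, 0.42),
    ("StSNP81", 0, 0, 15, 28, 132, 17, 0.25, 0.08, 0.4),
    ("StSNP66", 5, 140, 41, 0, 0, 6, 0.97, 0.7, 0.38),
    ("StSNP113", 7, 140, 38, 0, 0, 7, 0.96, 0.71, 0.38),
    ("StSNP120", 13, 145, 31, 0, 0, 3, 0.93, 0.73, 0.38),
    ("StSNP65", 0, 1, 135, 44, 0, 2, 1.0, 0.44, 0.38),
    ("StSNP75", 0, 0, 1, 37, 150, 4, 0.2, 0.05, 0.32),
    ("StSNP159", 144, 33, 1, 0, 0, 14, 0.19, 0.95, 0.31),
    ("StSNP160", 30, 154, 2, 0, 0, 6, 0.84, 0.79, 0.29),
    ("StSNP102", 160, 22, 7, 0, 0, 3, 0.15, 0.95, 0.27),
    ("StSNP123", 149, 26, 0, 1, 0, 16, 0.15, 0.96, 0.26),
    ("StSNP126", 150, 26, 0, 1, 0, 15, 0.15, 0.96, 0.26),
    ("StSNP36", 29, 160, 0, 0, 0, 3, 0.85, 0.79, 0.26),
    ("StSNP122", 15, 168, 7, 0, 0, 2, 0.92, 0.76, 0.21),
    ("StSNP48", 0, 0, 0, 22, 166, 4, 0.12, 0.03, 0.21),
    ("StSNP28", 167, 22, 0, 0, 0, 3, 0.12, 0.97, 0.21),
    ("StSNP29", 163, 19, 0, 0, 0, 10, 0.1, 0.97, 0.19),
    ("StSNP31", 169, 16, 3, 0, 0, 2, 0.1, 0.97, 0.18),
    ("StSNP64", 175, 15, 0, 0, 0, 2, 0.08, 0.98, 0.15),
    ("StSNP60", 176, 14, 0, 0, 0, 2, 0.07, 0.98, 0.14),
    ("StSNP50", 0, 180, 10, 0, 0, 2, 1.0, 0.74, 0.1),
    ("StSNP116", 2, 172, 5, 2, 0, 11, 0.99, 0.74, 0.1),
    ("StSNP144", 0, 0, 0, 8, 181, 3, 0.04, 0.01, 0.08),
    ("StSNP138", 0, 0, 0, 8, 182, 2, 0.04, 0.01, 0.08),
    ("StSNP20", 4, 182, 2, 0, 0, 4, 0.98, 0.75, 0.06),
    ("StSNP117", 0, 2, 177, 3, 0, 10, 1.0, 0.5, 0.05),
    ("StSNP150", 185, 5, 0, 0, 0, 2, 0.03, 0.99, 0.05),
    ("StSNP79", 1, 188, 1, 0, 0, 2, 0.99, 0.75, 0.02),
    ("StSNP63", 190, 0, 0, 0, 0, 2, 0.0, 1.0, 0.0),
    ("StSNP139", 0, 0, 190, 0, 0, 2, 1.0, 0.5, 0.0),)

_COLUMNS = ["marker", "n0", "n1", "n2", "n3", "n4", "n_missing",
            "OH_printed", "MA_printed", "PIC_printed"]


def load_parms_snp_panel() -> pd.DataFrame:
    """Return the reference panel as a DataFrame indexed by marker name.

    Columns ``n0``..``n4`` are dosage-class sample counts, ``n_missing``
    the no-call count, and ``OH_printed``/``MA_printed``/``PIC_printed``
    the two-decimal statistics as published.
    """
    df = pd.DataFrame.from_records(list(PARMS_SNP_PANEL), columns=_COLUMNS)
    return df.set_index("marker")


def panel_counts() -> pd.DataFrame:
    """Dosage-class counts only (n0..n4, n_missing), indexed by marker."""
    return load_parms_snp_panel()[["n0", "n1", "n2", "n3", "n4", "n_missing"]]


def expand_counts_to_matrix(counts: pd.DataFrame, prefix: str = "S",
                            drop_empty_samples: bool = False) -> pd.DataFrame:
    """Expand per-marker class counts into a samples x markers dosage matrix.

    Builds, for each marker, a column holding ``n0`` zeros, ``n1`` ones, ...
    followed by ``n_missing`` missing cells (NaN).  Markers may disagree on
    total sample number (published tables often do); the matrix is padded
    with missing cells to the largest total.  Sample identities are
    synthetic placeholders: the expansion preserves per-marker tallies,
    which is all the marker-level statistics consume, but any cross-marker
    per-sample structure is an artefact.  With ``drop_empty_samples`` the
    padding rows that end up missing at every marker are removed (useful
    when the matrix feeds distance or clustering stages); this trims the
    per-marker missing tallies but leaves every called count intact.
    """
    totals = counts[["n0", "n1", "n2", "n3", "n4", "n_missing"]].sum(axis=1)
    n_rows = int(totals.max())
    data = {}
    for marker, row in counts.iterrows():
        col = []
        for d in range(5):
            col.extend([float(d)] * int(row[f"n{d}"]))
        col.extend([float("nan")] * (n_rows - len(col)))
        data[marker] = col
    index = [f"{prefix}{i + 1}" for i in range(n_rows)]
    matrix = pd.DataFrame(data, index=index)
    if drop_empty_samples:
        matrix = matrix.dropna(how="all")
    return matrix
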