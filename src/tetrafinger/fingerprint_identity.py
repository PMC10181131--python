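"""SNP fingerprints and variety-identity analysis.

A fingerprint is a sample's dosage vector restricted to the most
informative loci (PIC above a threshold, default 0.6), serialised as a
compact code of digits 0-4 with ``N`` for missing.  Identity analysis
compares differently-named samples for synonyms (identical genotypes
under different names) and identically-named samples for homonyms (one
name covering genetically distinct material) — the mislabelling modes
that vegetatively propagated collections accumulate.

A synonym call requires both zero genetic distance on the full marker
panel and fingerprint identity on sufficiently many mutually called
loci; pairs at distance zero with too few comparable loci are reported
as unresolved rather than identical.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .diversity import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class FingerprintTable:
    """Per-sample dosage fingerprints over a fixed, ordered locus list."""

    loci: list[str]
    table: pd.DataFrame  # samples x loci dosage values

    def code(self, sample: str) -> str:
        """Compact fingerprint string: digits 0-4, N for missing."""
        row = self.table.loc[sample]
        return "".join("N" if pd.isna(v) else str(int(v)) for v in row)

    def codes(self) -> pd.Series:
        return pd.Series({s: self.code(s) for s in self.table.index})


@dataclass
class IdentityReport:
    """Synonym / homonym / unresolved calls over named samples."""

    synonyms: list[dict] = field(default_factory=list)
    homonym_groups: list[dict] = field(default_factory=list)
    unresolved: list[dict] = field(default_factory=list)
    concordant_replicates: list[dict] = field(default_factory=list)

    @property
    def synonym_pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted((s["sample_a"], s["sample_b"])))
                for s in self.synonyms}

    @property
    def homonym_names(self) -> set[str]:
        return {g["name"] for g in self.homonym_groups}

    def to_dict(self) -> dict:
        return {"synonyms": self.synonyms,
                "homonym_groups": self.homonym_groups,
                "unresolved": self.unresolved,
                "concordant_replicates": self.concordant_replicates}


def select_fingerprint_loci(stats: pd.DataFrame,
                            pic_threshold: float = 0.6) -> list[str]:
    """Loci with PIC strictly above the threshold, ordered by descending
    PIC then marker name (deterministic)."""
    chosen = stats.loc[stats["PIC"] > pic_threshold, ["PIC"]].reset_index()
    marker_col = chosen.columns[0]  # index name ("marker") or "index"
    ordered = chosen.sort_values(["PIC", marker_col], ascending=[False, True],
                                 kind="mergesort")
    loci = ordered[marker_col].tolist()
    logger.info("fingerprint loci: %d of %d markers with PIC > %g",
                len(loci), len(stats), pic_threshold)
    return loci


def build_fingerprints(matrix: pd.DataFrame,
                       loci: list[str]) -> FingerprintTable:
    """Restrict the dosage matrix to the fingerprint loci."""
    unknown = [m for m in loci if m not in matrix.columns]
    if unknown:
        raise KeyError(f"loci absent from matrix: {unknown}")
    return FingerprintTable(loci=list(loci), table=matrix[list(loci)].copy())


def _fingerprints_match(fa: pd.Series, fb: pd.Series,
                        min_shared_loci: int) -> tuple[bool, int]:
    both = fa.notna() & fb.notna()
    n_shared = int(both.sum())
    if n_shared < min_shared_loci:
        return False, n_shared
    return bool((fa[both] == fb[both]).all()), n_shared


def identify_varieties(fingerprints: FingerprintTable,
                       distances: DistanceMatrix,
                       names: dict[str, str],
                       min_shared_loci: int = 10) -> IdentityReport:
    """Classify sample pairs into synonyms, homonyms and unresolved.

    ``distances`` should come from the full (post-monomorphic-drop)
    marker panel, ``fingerprints`` from the PIC-selected loci.  A
    differently-named pair is a synonym candidate when its panel distance
    is 0 and its fingerprints agree on at least ``min_shared_loci``
    mutually called loci; with fewer comparable loci the pair is
    unresolved.  Identically-named samples form a homonym group when any
    pairwise distance is positive; identically-named samples at distance
    0 are logged as concordant replicates.
    """
    report = IdentityReport()
    samples = list(fingerprints.table.index)
    missing = [s for s in samples if s not in names]
    if missing:
        raise KeyError(f"no variety name for samples: {missing}")

    for a, b in itertools.combinations(samples, 2):
        d = distances.get(a, b)
        same_name = names[a] == names[b]
        if pd.isna(d):
            report.unresolved.append(
                {"sample_a": a, "sample_b": b, "reason": "no shared loci"})
            continue
        if same_name:
            continue  # handled in the homonym pass below
        if d == 0.0:
            match, n_shared = _fingerprints_match(
                fingerprints.table.loc[a], fingerprints.table.loc[b],
                min_shared_loci)
            if n_shared < min_shared_loci:
                report.unresolved.append(
                    {"sample_a": a, "sample_b": b,
                     "shared_loci": n_shared,
                     "reason": "distance 0 on too few shared loci"})
            elif match:
                report.synonyms.append(
                    {"sample_a": a, "sample_b": b,
                     "name_a": names[a], "name_b": names[b],
                     "distance": 0.0, "shared_loci": n_shared,
                     "fingerprint": fingerprints.code(a)})

    by_name: dict[str, list[str]] = {}
    for s in samples:
        by_name.setdefault(names[s], []).append(s)
    for name, members in by_name.items():
        if len(members) < 2:
            continue
        pair_info = []
        any_distinct = False
        for a, b in itertools.combinations(members, 2):
            d = distances.get(a, b)
            differing = []
            fa, fb = fingerprints.table.loc[a], fingerprints.table.loc[b]
            both = fa.notna() & fb.notna()
            differing = [loc for loc in fingerprints.loci
                         if both[loc] and fa[loc] != fb[loc]]
            pair_info.append({"sample_a": a, "sample_b": b,
                              "distance": None if pd.isna(d) else float(d),
                              "differing_loci": differing})
            if not pd.isna(d) and d > 0:
                any_distinct = True
        if any_distinct:
            report.homonym_groups.append(
                {"name": name, "members": members, "pairs": pair_info})
        else:
            report.concordant_replicates.append(
                {"name": name, "members": members})
            logger.info("name %r: %d concordant replicate samples",
                        name, len(members))
    return report
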