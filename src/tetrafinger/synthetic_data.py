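"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the data a tetraploid SNP-marker study produces
but does not usually deposit:

* dosage matrices under tetraploid Hardy-Weinberg equilibrium (per-marker
  allele-B frequency q, per-sample dosage ~ Binomial(4, q));
* two-channel endpoint-fluorescence signals with multiplicative
  log-normal noise and a small additive background, so the allele-B
  signal fraction stays inside (0, 1);
* toy cohort VCFs (plus a matching FASTA) with "perfect SNP" candidates
  planted by construction, flanking-variant violators, and background
  sites failing at least one quality criterion.

Every generator returns a :class:`SimTruth` carrying the planted answer
so downstream recovery can be scored exactly.  Identical seeds give
identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (GenomeSequence, VariantCohort, VariantRecord,
                         write_fasta, write_vcf)


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated data."""

    rng_seed: int
    q_by_marker: dict[str, float] = field(default_factory=dict)
    true_matrix: pd.DataFrame | None = None
    perfect_ids: set[str] = field(default_factory=set)
    flank_violator_ids: set[str] = field(default_factory=set)
    synonym_pairs: set[tuple[str, str]] = field(default_factory=set)
    homonym_groups: dict[str, list[str]] = field(default_factory=dict)
    sample_names: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rng_seed": self.rng_seed,
            "q_by_marker": self.q_by_marker,
            "perfect_ids": sorted(self.perfect_ids),
            "flank_violator_ids": sorted(self.flank_violator_ids),
            "synonym_pairs": sorted(map(list, self.synonym_pairs)),
            "homonym_groups": self.homonym_groups,
            "sample_names": self.sample_names,
        }


def _draw_q(q_dist, n: int, rng: np.random.Generator) -> np.ndarray:
    """Resolve a q-distribution spec: a constant, ("uniform", lo, hi),
    ("beta", a, b), or a callable(rng, size)."""
    if callable(q_dist):
        q = np.asarray(q_dist(rng, n), dtype=float)
    elif isinstance(q_dist, (int, float)):
        q = np.full(n, float(q_dist))
    elif isinstance(q_dist, (tuple, list)) and len(q_dist) == 3:
        kind, a, b = q_dist
        if kind == "uniform":
            q = rng.uniform(a, b, size=n)
        elif kind == "beta":
            q = rng.beta(a, b, size=n)
        else:
            raise ValueError(f"unknown q distribution kind {kind!r}")
    else:
        raise ValueError(f"invalid q distribution spec {q_dist!r}")
    if ((q < 0) | (q > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    return q


def simulate_dosage_matrix(n_samples: int, n_markers: int,
                           q_dist=("uniform", 0.1, 0.9),
                           missing_rate: float = 0.02,
                           seed: int = 0) -> tuple[pd.DataFrame, SimTruth]:
    """Tetraploid-HWE dosage matrix: dosage ~ Binomial(4, q_j) per marker.

    Cells go missing independently with ``missing_rate``.  Returns the
    observed matrix (NaN for missing) and the truth (q per marker and the
    complete matrix before masking).
    """
    if n_samples < 1 or n_markers < 1:
        raise ValueError("n_samples and n_markers must be >= 1")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    q = _draw_q(q_dist, n_markers, rng)
    dosages = rng.binomial(4, q[None, :], size=(n_samples, n_markers)).astype(float)
    samples = [f"S{i + 1}" for i in range(n_samples)]
    markers = [f"M{j + 1}" for j in range(n_markers)]
    complete = pd.DataFrame(dosages, index=samples, columns=markers)
    observed = complete.copy()
    if missing_rate > 0:
        mask = rng.random(size=dosages.shape) < missing_rate
        observed = observed.mask(mask)
    truth = SimTruth(rng_seed=seed,
                     q_by_marker=dict(zip(markers, map(float, q))),
                     true_matrix=complete)
    return observed, truth


def simulate_signals(matrix: pd.DataFrame, gain_A: float = 1000.0,
                     gain_B: float = 1000.0, noise_sd: float = 0.05,
                     background: float = 0.05,
                     seed: int = 0) -> pd.DataFrame:
    """Two-channel endpoint fluorescence for a dosage matrix.

    FAM reports the A allele and HEX the B allele:
    ``FAM = gain_A * (4 - d + background) * exp(e1)`` and
    ``HEX = gain_B * (d + background) * exp(e2)`` with
    ``e ~ Normal(0, noise_sd^2)``.  The additive background keeps the
    signal fraction strictly inside (0, 1) at d = 0 and 4.  Missing
    dosages produce background-only intensities on both channels.
    Returns a long-format table (sample, marker, fam, hex).
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if gain_A <= 0 or gain_B <= 0:
        raise ValueError("gains must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for marker in matrix.columns:
        for sample in matrix.index:
            d = matrix.loc[sample, marker]
            e1, e2 = rng.normal(0.0, noise_sd, size=2)
            if pd.isna(d):
                a_level, b_level = background, background
            else:
                a_level, b_level = 4.0 - float(d) + background, float(d) + background
            rows.append({"sample": sample, "marker": marker,
                         "fam": gain_A * a_level * math.exp(e1),
                         "hex": gain_B * b_level * math.exp(e2)})
    return pd.DataFrame(rows)


def _planted_genotype_counts(n_samples: int, rng: np.random.Generator,
                             maf_range=(0.42, 0.5)) -> tuple[int, int, int, int]:
    """Class counts (n0, n_het, n4, n_missing) satisfying the perfect-SNP
    criteria by construction: miss rate 0.1, duplex fraction 0.3, and an
    allele-B frequency drawn inside ``maf_range``."""
    n_called = math.ceil(0.9 * n_samples)          # miss rate 0.1 < 0.2
    n_het = math.floor(0.3 * n_called)             # het fraction < 0.4
    m = rng.uniform(*maf_range)
    n4 = round(n_called * m - n_het / 2.0)         # freq_B = m
    n4 = min(max(n4, 0), n_called - n_het)
    n0 = n_called - n_het - n4
    freq_b = (2 * n_het + 4 * n4) / (4 * n_called)
    if not 0.4 < min(freq_b, 1 - freq_b) <= 0.5:
        raise AssertionError("planted MAF construction failed")
    return n0, n_het, n4, n_samples - n_called


def _site_dosages(kind: str, n_samples: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-sample allele-B dosage (or NaN) for one simulated site."""
    d = np.full(n_samples, np.nan)
    if kind in ("perfect", "violator"):
        n0, n_het, n4, _ = _planted_genotype_counts(n_samples, rng)
        vals = np.array([0.0] * n0 + [2.0] * n_het + [4.0] * n4
                        + [np.nan] * (n_samples - n0 - n_het - n4))
        return rng.permutation(vals)
    if kind == "partner_lowmaf":
        d[:] = 0.0
        d[rng.integers(n_samples)] = 1.0
        return d
    defect = rng.integers(3)
    if defect == 0:        # low MAF
        d[:] = 0.0
        d[rng.random(n_samples) < 0.05] = 1.0
    elif defect == 1:      # high missingness
        d = _site_dosages("perfect", n_samples, rng)
        d[rng.random(n_samples) < 0.5] = np.nan
    else:                  # all heterozygous
        d[:] = 2.0
    return d


def simulate_cohort_vcf(n_samples: int = 50, n_sites: int = 50,
                        planted_perfect: int = 5, flank_violators: int = 3,
                        mean_depth: float = 30.0, seed: int = 0,
                        out_dir: str | Path = ".",
                        contig_length: int = 100_000,
                        n_contigs: int = 2,
                        flank_bp: int = 100) -> tuple[Path, Path, SimTruth]:
    """Toy genome plus cohort VCF with planted perfect-SNP truth.

    Planted-perfect sites satisfy all four selection criteria by
    construction; flanking violators satisfy the MAF/missingness/
    heterozygosity criteria but carry a partner variant within
    ``flank_bp`` bp; every remaining site fails at least one of the first
    three criteria.  Each partner variant consumes one site from the
    background budget, so ``planted_perfect + 2*flank_violators`` must
    not exceed ``n_sites``.  Per-sample read depth is Poisson with mean
    ``mean_depth``, split between alleles by the true dosage; a sample
    with zero reads at a site is recorded as a missing call.

    Writes ``cohort.vcf`` and ``genome.fa`` under ``out_dir`` and returns
    their paths with the truth.
    """
    if planted_perfect + 2 * flank_violators > n_sites:
        raise ValueError("n_sites too small for the requested planted sites "
                         "(each flanking violator also needs a partner site)")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_background = n_sites - planted_perfect - 2 * flank_violators
    slot_gap = 2 * flank_bp + 50
    n_slots = planted_perfect + flank_violators + n_background
    per_contig = (contig_length - 2 * slot_gap) // slot_gap
    if per_contig * n_contigs < n_slots:
        raise ValueError("genome too short to place sites with the required "
                         "spacing; increase contig_length or n_contigs")

    contigs = [GenomeSequence(
        f"chr{c + 1:02d}",
        "".join(rng.choice(list("ACGT"), size=contig_length)))
        for c in range(n_contigs)]

    kinds = (["perfect"] * planted_perfect + ["violator"] * flank_violators
             + ["background"] * n_background)
    kinds = list(rng.permutation(kinds))

    slots = []
    for c in range(n_contigs):
        for s in range(per_contig):
            slots.append((contigs[c].name, slot_gap + s * slot_gap))
            if len(slots) == n_slots:
                break
        if len(slots) == n_slots:
            break

    samples = [f"S{i + 1}" for i in range(n_samples)]
    truth = SimTruth(rng_seed=seed)
    site_rows = []   # (chrom, pos, dosages)
    for kind, (chrom, pos) in zip(kinds, slots):
        dos = _site_dosages(kind, n_samples, rng)
        site_rows.append((chrom, pos, dos))
        key = f"{chrom}:{pos}"
        if kind == "perfect":
            truth.perfect_ids.add(key)
        elif kind == "violator":
            truth.flank_violator_ids.add(key)
            partner_pos = pos + rng.integers(20, flank_bp)
            site_rows.append((chrom, int(partner_pos),
                              _site_dosages("partner_lowmaf", n_samples, rng)))
    site_rows.sort(key=lambda r: (r[0], r[1]))

    bases = "ACGT"
    records = []
    for chrom, pos, dos in site_rows:
        seq = next(c for c in contigs if c.name == chrom)
        ref = seq.sequence[pos - 1]
        alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
        gts: list[tuple[int, ...] | None] = []
        ads: list[tuple[int, ...] | None] = []
        for i in range(len(samples)):
            d = dos[i]
            depth = rng.poisson(mean_depth)
            if math.isnan(d) or depth == 0:
                gts.append(None)
                ads.append((0, 0))
                continue
            n_alt_reads = rng.binomial(depth, d / 4.0)
            ads.append((depth - n_alt_reads, n_alt_reads))
            gts.append(tuple([1] * int(d) + [0] * (4 - int(d))))
        records.append(VariantRecord(chrom=chrom, pos=pos, ref=ref,
                                     alts=(alt,), genotypes=gts, depths=ads))
    cohort = VariantCohort(samples=samples, records=records,
                           contig_lengths={c.name: len(c) for c in contigs})
    vcf_path = out_dir / "cohort.vcf"
    fasta_path = out_dir / "genome.fa"
    write_vcf(cohort, vcf_path)
    write_fasta(contigs, fasta_path)
    return vcf_path, fasta_path, truth


def inject_identity_cases(matrix: pd.DataFrame, names: list[str] | None = None,
                          n_synonyms: int = 0, n_homonyms: int = 0,
                          seed: int = 0
                          ) -> tuple[pd.DataFrame, dict[str, str], SimTruth]:
    """Plant synonym and homonym cases into a dosage matrix.

    A synonym duplicates an existing sample's genotype row under a fresh
    sample id and a fresh variety name (genetic distance 0, different
    names).  A homonym reassigns an existing variety name to a
    genotypically distinct sample (same name, distance > 0).  Returns the
    augmented matrix, the sample-id -> variety-name map, and the truth.
    """
    n = len(matrix)
    if n_synonyms + n_homonyms > n:
        raise ValueError("requested more identity cases than samples")
    rng = np.random.default_rng(seed)
    names = list(matrix.index) if names is None else list(names)
    if len(names) != n:
        raise ValueError("names must match the number of samples")
    name_map = dict(zip(matrix.index, names))
    truth = SimTruth(rng_seed=seed)
    out = matrix.copy()

    donors = rng.choice(n, size=n_synonyms + n_homonyms, replace=False)
    syn_donors, hom_targets = donors[:n_synonyms], donors[n_synonyms:]

    for i, donor_idx in enumerate(syn_donors):
        donor = matrix.index[donor_idx]
        new_id = f"SYN{i + 1}"
        out.loc[new_id] = matrix.loc[donor]
        name_map[new_id] = f"{name_map[donor]}-alias"
        truth.synonym_pairs.add(tuple(sorted((donor, new_id))))

    for i, target_idx in enumerate(hom_targets):
        target = matrix.index[target_idx]
        # pick a genotypically distinct sample to mislabel with target's name
        candidates = [s for s in matrix.index
                      if s != target
                      and not matrix.loc[s].equals(matrix.loc[target])
                      and s not in {m for g in truth.homonym_groups.values()
                                    for m in g}
                      and all(s not in p for p in truth.synonym_pairs)]
        if not candidates:
            raise ValueError("no genotypically distinct sample left to mislabel")
        other = candidates[rng.integers(len(candidates))]
        name_map[other] = name_map[target]
        truth.homonym_groups[name_map[target]] = [target, other]

    truth.sample_names = dict(name_map)
    truth.true_matrix = out.copy()
    return out, name_map, truth
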