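"""Readers and writers for every external format the pipeline touches.

VCF 4.x is handled through :mod:`pysam`, FASTA through :mod:`pyfaidx`
(read) and Biopython (write), and delimited dosage / fluorescence tables
through :mod:`pandas`.  Positions are 1-based in VCF records, matching
the format; window arithmetic elsewhere converts to 0-based half-open.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

MISSING_DOSAGE_TOKENS = ("NA", "", ".")

_IUPAC = set("ACGTRYSWKMBDHVN")


@dataclass
class GenomeSequence:
    """One reference contig: a name and its nucleotide sequence."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.name!r} has an empty sequence")
        bad = set(self.sequence.upper()) - _IUPAC
        if bad:
            raise ValueError(
                f"contig {self.name!r} contains non-IUPAC characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class VariantRecord:
    """One SNP site with per-sample genotype calls and allele read depths.

    ``pos`` is 1-based as in VCF.  ``genotypes[i]`` is a tuple of allele
    indices (ploidy 2 or 4) or ``None`` for a missing call; ``depths[i]``
    is a tuple of per-allele read counts (REF first) or ``None`` when the
    file carries no AD field.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: list[tuple[int, ...] | None] = field(default_factory=list)
    depths: list[tuple[int, ...] | None] = field(default_factory=list)
    vid: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")
        n_alleles = 1 + len(self.alts)
        for ad in self.depths:
            if ad is not None and len(ad) != n_alleles:
                raise ValueError(
                    f"{self.key}: depth vector length {len(ad)} != {n_alleles} alleles")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) > 1

    @property
    def has_depths(self) -> bool:
        return any(ad is not None for ad in self.depths)


@dataclass
class VariantCohort:
    """An ordered collection of variant records over a fixed sample panel."""

    samples: list[str]
    records: list[VariantRecord]
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (plain or bgzipped) FASTA into a list of contigs."""
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    contigs = [GenomeSequence(name, str(fa[name][:])) for name in fa.keys()]
    names = [c.name for c in contigs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate contig names in {path}")
    logger.info("read %d contigs from %s", len(contigs), path)
    return contigs


def write_fasta(contigs: list[GenomeSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.name, description="")
               for c in contigs]
    SeqIO.write(records, str(path), "fasta")
    logger.info("wrote %d contigs to %s", len(contigs), path)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path) -> VariantCohort:
    """Read a VCF 4.x file into a :class:`VariantCohort`.

    Multiallelic sites are preserved as single records.  A file without a
    per-sample AD (allele depth) FORMAT field is read with a warning; the
    read-support quality filter is then unavailable for it.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    has_ad = "AD" in vf.header.formats
    if not has_ad:
        logger.warning(
            "%s carries no AD FORMAT field; read-support filters disabled", path)
    contig_lengths = {name: c.length for name, c in vf.header.contigs.items()
                      if c.length is not None}
    records: list[VariantRecord] = []
    for rec in vf:
        gts: list[tuple[int, ...] | None] = []
        ads: list[tuple[int, ...] | None] = []
        for s in samples:
            call = rec.samples[s]
            gt = call.get("GT")
            if gt is None or all(a is None for a in gt):
                gts.append(None)
            else:
                gts.append(tuple(0 if a is None else int(a) for a in gt))
            if has_ad:
                ad = call.get("AD")
                ads.append(None if ad is None or all(a is None for a in ad)
                           else tuple(int(a or 0) for a in ad))
            else:
                ads.append(None)
        records.append(VariantRecord(
            chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
            alts=tuple(rec.alts or ()), genotypes=gts, depths=ads,
            vid=rec.id))
    logger.info("read %d records, %d samples from %s",
                len(records), len(samples), path)
    return VariantCohort(samples=samples, records=records,
                         contig_lengths=contig_lengths)


def write_vcf(cohort: VariantCohort, path: str | Path) -> None:
    """Write a :class:`VariantCohort` as an uncompressed VCF 4.2 file."""
    header = pysam.VariantHeader()
    for name, length in cohort.contig_lengths.items():
        header.contigs.add(name, length=length)
    # contigs referenced by records but absent from contig_lengths
    for rec in cohort.records:
        if rec.chrom not in header.contigs:
            header.contigs.add(rec.chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer",
                       "Allelic depths for the ref and alt alleles")
    for s in cohort.samples:
        header.add_sample(s)
    out = pysam.VariantFile(str(path), "w", header=header)
    for rec in cohort.records:
        vrec = out.new_record(contig=rec.chrom, start=rec.pos - 1,
                              alleles=(rec.ref, *rec.alts), id=rec.vid)
        for i, s in enumerate(cohort.samples):
            gt = rec.genotypes[i]
            if gt is None:
                ploidy = 4 if any(g is not None and len(g) == 4
                                  for g in rec.genotypes) else 2
                vrec.samples[s]["GT"] = (None,) * ploidy
            else:
                vrec.samples[s]["GT"] = gt
            if rec.depths[i] is not None:
                vrec.samples[s]["AD"] = rec.depths[i]
        out.write(vrec)
    out.close()
    logger.info("wrote %d records to %s", len(cohort.records), path)


# ---------------------------------------------------------------------------
# Dosage matrices and signal tables


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_dosage_matrix(path: str | Path) -> pd.DataFrame:
    """Read a samples x markers dosage-score table.

    First column: sample name; header row: marker names; cells in
    {0,1,2,3,4} or one of the missing tokens ``NA``, ``.``, empty.
    Duplicate sample names are allowed (homonym studies need them) but
    logged.  Returns a float DataFrame with NaN for missing.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                     keep_default_na=False)
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns,
                       dtype=float)
    for col in df.columns:
        for sample, raw in df[col].items():
            token = str(raw).strip()
            if token in MISSING_DOSAGE_TOKENS:
                out.loc[sample, col] = math.nan
                continue
            try:
                val = float(token)
            except ValueError:
                raise ValueError(
                    f"cell ({sample}, {col}) = {raw!r} is not a dosage in 0..4")
            if val not in (0.0, 1.0, 2.0, 3.0, 4.0):
                raise ValueError(
                    f"cell ({sample}, {col}) = {raw!r} outside dosage range 0..4")
            out.loc[sample, col] = val
    dups = out.index[out.index.duplicated()].unique().tolist()
    if dups:
        logger.warning("duplicate sample names in %s: %s", path, dups)
    logger.info("read %dx%d dosage matrix from %s", *out.shape, path)
    return out


def write_dosage_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a dosage matrix; missing cells become ``NA``."""
    fmt = matrix.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    fmt.to_csv(path, sep=_sep_for(path))
    logger.info("wrote %dx%d dosage matrix to %s", *matrix.shape, path)


def read_signal_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format fluorescence table: sample, marker, fam, hex."""
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"sample", "marker", "fam", "hex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"signal table {path} lacks columns: {sorted(missing)}")
    if ((df["fam"] < 0) | (df["hex"] < 0)).any():
        raise ValueError("fluorescence intensities must be non-negative")
    logger.info("read %d signal records from %s", len(df), path)
    return df


def write_signal_table(signals: pd.DataFrame, path: str | Path) -> None:
    signals.to_csv(path, sep=_sep_for(path), index=False)
    logger.info("wrote %d signal records to %s", len(signals), path)


# ---------------------------------------------------------------------------
# Newick export

_NEEDS_QUOTE = re.compile(r"[\s()\[\]'\":;,]")


def _newick_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_length(x: float) -> str:
    if x < 0:
        raise ValueError(f"negative branch length {x}")
    return f"{x:.6g}"


def write_newick(tree) -> str:
    """Serialise a :class:`~tetrafinger.diversity.Dendrogram` to Newick.

    Branch lengths are parent height minus child height, printed with six
    significant digits; labels are quoted per Newick rules when needed.
    """
    seen: set[int] = set()

    def render(node, parent_height: float | None) -> str:
        if id(node) in seen:
            raise ValueError("cyclic tree structure")
        seen.add(id(node))
        if node.children:
            inner = ",".join(render(c, node.height) for c in node.children)
            body = f"({inner})"
        else:
            body = _newick_label(node.label or "")
        if parent_height is None:
            return body
        return f"{body}:{_format_length(parent_height - node.height)}"

    return render(tree.root, None) + ";"
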