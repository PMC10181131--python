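"""End-to-end pipeline runs with a reproducibility manifest.

Two entry points mirror the two halves of the workflow:

* :func:`run_marker_discovery` — cohort VCF + reference FASTA in,
  perfect-SNP candidate VCF and audit reports out;
* :func:`run_genotype_analysis` — fluorescence signals (or a dosage
  matrix) in; marker statistics, fingerprints, identity report, UPGMA
  dendrogram and PCA scores out.

Each run writes a JSON manifest recording the configuration, input file
digests, per-stage record counts, package version and seed, so a run can
be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .dosage_calling import DosageMixtureModel
from .diversity import euclidean_distances, pca_scores, upgma
from .fingerprint_identity import (build_fingerprints, identify_varieties,
                                   select_fingerprint_loci)
from .io_formats import (VariantCohort, read_dosage_matrix, read_signal_table,
                         read_vcf, write_dosage_matrix, write_newick,
                         write_vcf)
from .marker_stats import (compute_marker_stats, drop_monomorphic,
                           summarize_markers)
from .snp_filtering import filter_high_quality, select_perfect_snps

logger = logging.getLogger(__name__)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config: dict
    seed: int
    version: str = __version__
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> stage
    stage_counts: dict[str, int] = field(default_factory=dict)

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = _sha256(path)

    def add_output(self, path: str | Path, stage: str) -> None:
        self.outputs[str(path)] = stage

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class MarkerDiscoveryResult:
    perfect: list
    qc_report: pd.DataFrame
    criterion_report: dict[str, list[str]]
    manifest: RunManifest


def run_marker_discovery(vcf_path: str | Path,
                         config: RunConfig | None = None,
                         out_dir: str | Path = "discovery_out",
                         ) -> MarkerDiscoveryResult:
    """Cohort VCF -> high-quality filter -> perfect-SNP candidates.

    Writes ``perfect_snps.vcf``, ``site_qc.tsv``, ``criteria.json`` and
    ``manifest.json`` under ``out_dir``.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.rng_seed)
    manifest.add_input(vcf_path)

    cohort = read_vcf(vcf_path)
    manifest.stage_counts["input_sites"] = len(cohort)
    hq, qcs = filter_high_quality(cohort.records, len(cohort.samples),
                                  min_minor_reads=config.min_minor_reads,
                                  min_integrity=config.min_integrity)
    manifest.stage_counts["high_quality_sites"] = len(hq)
    perfect, criterion_report = select_perfect_snps(
        hq, len(cohort.samples), maf_min=config.maf_min,
        miss_max=config.miss_max, het_max=config.het_max,
        flank_bp=config.flank_bp, universe=cohort.records)
    manifest.stage_counts["perfect_snps"] = len(perfect)

    out_vcf = out_dir / "perfect_snps.vcf"
    write_vcf(VariantCohort(samples=cohort.samples, records=perfect,
                            contig_lengths=cohort.contig_lengths), out_vcf)
    manifest.add_output(out_vcf, "select_perfect_snps")

    qc_df = pd.DataFrame([{
        "site": q.key, "n_called": q.n_called, "integrity": q.integrity,
        "miss_rate": q.miss_rate, "maf": q.maf,
        "het_fraction": q.het_fraction,
        "minor_allele_reads": q.minor_allele_reads} for q in qcs])
    qc_path = out_dir / "site_qc.tsv"
    qc_df.to_csv(qc_path, sep="\t", index=False)
    manifest.add_output(qc_path, "filter_high_quality")

    crit_path = out_dir / "criteria.json"
    with open(crit_path, "w") as fh:
        json.dump(criterion_report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.add_output(crit_path, "select_perfect_snps")
    manifest.write(out_dir / "manifest.json")
    return MarkerDiscoveryResult(perfect=perfect, qc_report=qc_df,
                                 criterion_report=criterion_report,
                                 manifest=manifest)


@dataclass
class GenotypeAnalysisResult:
    matrix: pd.DataFrame
    stats: pd.DataFrame
    summary: dict
    reduced_matrix: pd.DataFrame
    fingerprints: object | None
    identity: object | None
    dendrogram: object | None
    pca: pd.DataFrame | None
    explained_variance: object | None
    manifest: RunManifest


def run_genotype_analysis(signals_path: str | Path | None = None,
                          dosages_path: str | Path | None = None,
                          names: dict[str, str] | None = None,
                          config: RunConfig | None = None,
                          out_dir: str | Path = "genotype_out",
                          ) -> GenotypeAnalysisResult:
    """Signals (or dosages) -> stats -> fingerprints -> identity -> tree.

    Exactly one of ``signals_path`` / ``dosages_path`` must be given.
    With a single sample the distance, dendrogram and identity stages are
    skipped with a warning.
    """
    if (signals_path is None) == (dosages_path is None):
        raise ValueError("provide exactly one of signals_path or dosages_path")
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.rng_seed)

    if signals_path is not None:
        manifest.add_input(signals_path)
        signals = read_signal_table(signals_path)
        results = DosageMixtureModel(signals).fit(
            posterior_threshold=config.posterior_threshold,
            peak_threshold=config.peak_threshold, seed=config.rng_seed)
        matrix = results.to_matrix()
        report_path = out_dir / "model_report.json"
        with open(report_path, "w") as fh:
            json.dump(results.model_report(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest.add_output(report_path, "dosage_calling")
        mat_path = out_dir / "dosages.csv"
        write_dosage_matrix(matrix, mat_path)
        manifest.add_output(mat_path, "dosage_calling")
    else:
        manifest.add_input(dosages_path)
        matrix = read_dosage_matrix(dosages_path)
    manifest.stage_counts["samples"] = len(matrix)
    manifest.stage_counts["markers"] = matrix.shape[1]

    stats = compute_marker_stats(matrix)
    summary = summarize_markers(stats)
    stats_path = out_dir / "marker_stats.tsv"
    stats.to_csv(stats_path, sep="\t", float_format="%.6g")
    manifest.add_output(stats_path, "marker_stats")
    summary_path = out_dir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.add_output(summary_path, "marker_stats")

    reduced = drop_monomorphic(matrix, stats)
    manifest.stage_counts["markers_after_monomorphic_drop"] = reduced.shape[1]

    loci = select_fingerprint_loci(stats.loc[reduced.columns]
                                   if len(reduced.columns) else stats,
                                   pic_threshold=config.pic_threshold)
    fingerprints = build_fingerprints(reduced, loci) if loci else None
    manifest.stage_counts["fingerprint_loci"] = len(loci)
    if fingerprints is not None:
        fp_path = out_dir / "fingerprints.csv"
        codes = fingerprints.codes()
        codes.rename("fingerprint").to_csv(fp_path)
        manifest.add_output(fp_path, "fingerprints")

    dendrogram = identity = pca_df = evr = None
    if len(reduced) >= 2 and reduced.shape[1] >= 1:
        distances = euclidean_distances(reduced)
        dist_path = out_dir / "distances.csv"
        distances.to_frame().to_csv(dist_path, float_format="%.6g")
        manifest.add_output(dist_path, "distances")
        if distances.is_complete:
            dendrogram = upgma(distances)
            tree_path = out_dir / "dendrogram.nwk"
            tree_path.write_text(write_newick(dendrogram) + "\n")
            manifest.add_output(tree_path, "upgma")
        else:
            logger.warning("incomplete distance matrix; dendrogram skipped")
        if fingerprints is not None:
            sample_names = names or {s: s for s in reduced.index}
            identity = identify_varieties(fingerprints, distances,
                                          sample_names)
            id_path = out_dir / "identity.json"
            with open(id_path, "w") as fh:
                json.dump(identity.to_dict(), fh, indent=2)
                fh.write("\n")
            manifest.add_output(id_path, "identity")
        n_comp = min(2, len(reduced) - 1) or 1
        pca_df, evr = pca_scores(reduced, n_components=n_comp)
        pca_path = out_dir / "pca_scores.csv"
        pca_df.to_csv(pca_path, float_format="%.6g")
        manifest.add_output(pca_path, "pca")
    else:
        logger.warning("fewer than 2 samples; distance/tree/PCA stages skipped")

    manifest.write(out_dir / "manifest.json")
    return GenotypeAnalysisResult(matrix=matrix, stats=stats, summary=summary,
                                  reduced_matrix=reduced,
                                  fingerprints=fingerprints, identity=identity,
                                  dendrogram=dendrogram, pca=pca_df,
                                  explained_variance=evr, manifest=manifest)
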