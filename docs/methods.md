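# Methods

## Scope and data model

`tetrafinger` operates on three representations of an autotetraploid SNP
panel: a cohort VCF with per-sample genotypes (ploidy 2 or 4) and allele
read depths (AD); a long-format two-channel fluorescence table
(sample, marker, FAM, HEX) from competitive allele-specific PCR; and a
samples × markers allele-B dosage matrix with values in {0,…,4} or
missing.  The dosage matrix is the central object: marker statistics,
fingerprints, distances, clustering and PCA all consume it.  VCF
positions are 1-based as in the format; all window arithmetic is 0-based
half-open, and the final partial window of a contig is kept and counted
like any other.

## Cohort-VCF filtering

The high-quality filter keeps biallelic sites whose cohort-wide read
support for the minor allele exceeds 3 reads and whose call integrity
(fraction of samples with a genotype) exceeds 85%.  Both thresholds, and
all four perfect-SNP thresholds below, are **strict** inequalities; the
boundary behaviour is pinned by tests.  "Minor-allele read support" is
interpreted cohort-wide — the sum over samples of the AD entry for the
cohort-minor allele — because at the low average depths typical of
reduced-representation sequencing (~10×) a per-sample reading would
reject nearly every site; a `use_read_support=False` switch disables the
criterion when AD is absent.

Perfect-SNP candidates are biallelic sites with MAF > 0.4 (allele copies
counted from called genotypes), miss rate < 0.2, heterozygous-sample
fraction < 0.4, and no other variant within ±100 bp (inclusive) on the
same contig.  The flanking catalogue is the full cohort VCF passed as
`universe`, so sites removed by earlier filters still veto their
neighbours.  Every rejected site is reported with the list of criteria
it failed.  SNP-rich windows are the `ceil(top_frac · n_windows)`
highest-count windows over all contigs jointly; all windows tied with
the cutoff count are flagged (and the tie logged) to avoid arbitrary
rank-order dependence.

## Dosage calling

The caller is a per-marker one-dimensional mixture model on the signal
fraction *hex/(fam+hex)*, arcsine-square-root transformed (variance
stabilisation for proportions).  For k = 1…5 a tied-variance Gaussian
mixture is fitted by EM (tolerance 1e-8 on the log-likelihood, max 500
iterations, 5 restarts: quantile initialisation, a k-means
initialisation for robustness under unbalanced class sizes, and jittered
quantiles; all seeded).  Means are kept sorted so components are
order-identified.

Model selection is BIC over *admissible* models: a k > 1 model is
admissible only if its adjacent means are at least
`MIN_COMPONENT_SEPARATION` apart — half the smallest gap between the
canonical class centres `arcsin(sqrt(d/4))`, ≈ 0.131.  Without this
constraint the tied-variance likelihood rewards splitting one tight
cluster into near-duplicate components, which would then be mapped to
two different dosage classes.  The selected components are matched
one-to-one to dosage classes by minimum total |mean − centre| distance
(a linear assignment, which is order-preserving in one dimension), so a
marker segregating only in classes 0/1/2 maps its three components to
those classes rather than to 0/2/4.

A sample is assigned the maximum-posterior dosage when that posterior is
≥ 0.6 (default), else left missing; the assignment rule uses ≥ so that
"missing iff posterior below threshold" holds exactly.  A sample exactly
midway between two equal components has posterior ½ and is therefore
missing.  If the largest component's weight exceeds the peak threshold
the marker is flagged non-segregating; the default threshold of 1.0
disables the flag.  Markers with fewer than 10 callable records are left
uncalled.  Channel orientation (which fluorophore reports allele A) is a
per-assay flag, default `fam-is-A`; the MA statistic downstream inverts
if it is set wrongly, so it is surfaced in the model and the CLI.

The caller is this package's own algorithm in the spirit of established
tetraploid genotype-calling tools; it does not attempt to reproduce any
particular tool's numerical output.

## Marker statistics

From the per-marker class tally n₀…n₄ over called samples
(missing calls excluded from every denominator):

* MA = Σ_d (4−d)·n_d / (4·n_called);
* OH = (n₁+n₂+n₃)/n_called;
* PIC = 1 − Σ_g (n_g/n_called)² over the five genotype classes.

The PIC here is genotype-class gene diversity, bounded by 0.8 (five
equal classes) and 0 iff a single class is observed.  This form — rather
than the classical four-term allele-based PIC — is the one whose values
reproduce the published per-marker table this package ships
(`tetrafinger.datasets`): on its StSNP54 row the class-frequency form
gives 0.70 while the allele-based form gives 0.65.  Comparisons against
printed two-decimal values use round-half-away-from-zero; internal
values stay full precision.  Markers with exactly one observed dosage
class are removed before distance and fingerprint analysis.

`expand_counts_to_matrix` turns a per-marker count table into a
per-sample matrix by listing each class contiguously; this preserves
every per-marker tally (the only thing marker-level statistics consume)
but any cross-marker per-sample structure in such a matrix is an
artefact of the expansion, so distances computed from it are not
biologically meaningful — they exercise the code path, nothing more.

## Fingerprints and identity

Fingerprint loci are markers with PIC strictly above 0.6, ordered by
descending PIC then name (deterministic).  A fingerprint is the dosage
vector over those loci, serialised as digits 0–4 with `N` for missing.
A synonym candidate is a differently-named pair with panel distance 0
**and** identical fingerprints on at least `min_shared_loci` (default
10) mutually called loci — requiring both mirrors the two-step argument
(dendrogram, then fingerprint) used in practice.  Pairs at distance 0
with fewer comparable loci are reported as unresolved rather than
identical.  Identically-named samples form a homonym group when any
pairwise distance is positive, with the differing loci listed;
identically-named samples at distance 0 are concordant replicates, not
errors.

## Distances, UPGMA, PCA

Euclidean distance uses pairwise-complete deletion: each pair is
compared on loci called in both samples, the shared-locus count is
recorded, and a pair sharing no loci gets a missing distance.  No
rescaling by shared-locus count is applied by default; a
`scale_by_shared` flag multiplies the squared distance by
n_loci/n_shared for sparse panels.

UPGMA is implemented directly (size-weighted average linkage) so that
tie-breaking is fully deterministic: among equally close cluster pairs,
the pair whose lexicographically smallest member label sorts first
merges, and children are ordered the same way.  Node height is half the
merging distance (cophenetic convention), so the tree is ultrametric and
leaf-to-leaf path length equals the cluster distance; Newick export
writes branch lengths as parent height minus child height with six
significant digits.  scipy's average-linkage heights serve as an
independent oracle in the tests, never as the implementation.

PCA mean-imputes missing cells per marker (logged), centres columns, and
uses a full SVD; the sign convention makes the largest-magnitude loading
of each component positive.  An all-constant matrix yields zero scores
and zero explained variance rather than an error.

## Synthetic data

The generators define the conditions under which the pipeline is
validated:

* **Dosage matrices**: per-marker allele-B frequency q (constant,
  uniform, beta, or user callable), per-sample dosage ~ Binomial(4, q)
  — tetraploid Hardy–Weinberg equilibrium.  Real breeding panels are
  not in HWE, but every statistic the pipeline computes is
  frequency-free, so the model only matters for recovery tests, where
  its closed forms (mean dosage 4q; OH at q = ½ equal to
  1 − 2·(½)⁴ = 0.875) serve as oracles.  Default missingness 2%.
* **Signals**: FAM = gain·(4−d+b)·e^ε, HEX = gain·(d+b)·e^ε with
  ε ~ N(0, 0.05²) by default and additive background b = 0.05, chosen so
  the signal fraction is strictly inside (0,1) at d ∈ {0,4} —
  mirroring competitive-PCR endpoint reads.  Missing dosages emit
  background-only intensities on both channels; intensity-based
  no-template detection is out of scope.
* **Cohort VCFs**: 2 contigs × 100 kb by default, sites laid out in
  slots 250 bp apart so planted "perfect" sites are isolated by
  construction.  Perfect sites get miss rate 0.1, duplex fraction 0.3
  and allele-B frequency drawn in (0.42, 0.5] — satisfying all four
  selection criteria deterministically.  Flanking violators satisfy
  criteria 1–3 but receive a partner variant 20–100 bp away (the partner
  consumes one background-site slot, so
  planted + 2·violators ≤ n_sites).  Background sites fail at least one
  of: low MAF, 50% missingness, all-heterozygous.  Per-sample depth is
  Poisson (default mean 30), split binomially by true dosage; zero-depth
  samples become missing calls, so `mean_depth=1` reproduces an
  integrity-filter-dominated regime.
* **Identity cases**: synonyms duplicate a genotype row under a fresh
  sample id and name; homonyms reassign an existing name to a
  genotypically distinct sample.  Truth (pairs, groups, name map) is
  returned alongside.

What passing these tests shows — and does not: recovery results hold
under independent markers, HWE dosages and log-normal signal noise; real
panels add linkage, population structure, plate effects and
null-allele/flanking-polymorphism failures that the generators do not
model.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: the published
71-marker × 190-sample panel, simulated cohorts of 50 samples × 50
sites, dosage-caller recovery at 500 records per marker, and 8-sample
matrices for clustering oracles.  Every stochastic component takes an
explicit seed (`numpy.random.default_rng`); identical seeds give
byte-identical outputs, which the pipeline manifest (config digest,
input hashes, stage counts) makes checkable.

## Known limitations

* The dosage caller assumes a tied variance across classes on the
  transformed scale; strongly heteroscedastic assays may need per-class
  variances (config-exposed internals make this a contained change).
* Synonym detection requires exact distance 0; near-clonal pairs
  (somatic mutations, genotyping errors) are not merged.
* Multiallelic sites are partitioned out, not dosage-called.
* The paper-style per-sample MA/OH summaries (one value per variety) are
  not implemented; all statistics are per marker.
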