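# tetrafinger

SNP-marker selection, tetraploid allele-dosage calling and DNA-fingerprint
variety identification for autotetraploid crops such as potato
(*Solanum tuberosum* L.).

## The problem

Autotetraploid varieties are vegetatively propagated and morphologically
similar, so collections accumulate **synonyms** (one clone under several
names) and **homonyms** (one name covering genetically distinct material).
A small panel of informative SNP markers, assayed by competitive
allele-specific PCR (KASP/PARMS) and called as allele dosages, gives a
cheap and robust fingerprint for variety identification and DUS testing.
`tetrafinger` implements the full downstream workflow:

1. **Marker discovery** from a cohort VCF: high-quality site filtering
   (cohort minor-allele read support > 3, call integrity > 85%),
   biallelic/multiallelic partition, SNP density and SNP-rich windows,
   and "perfect SNP" selection — biallelic sites with MAF > 0.4,
   miss rate < 0.2, heterozygous fraction < 0.4 and no other variant
   within ±100 bp, suitable for PCR assay conversion.
2. **Dosage calling** from two-channel endpoint fluorescence (FAM/HEX).
   In a tetraploid the allele-B copy number per sample is 0–4
   (AAAA … BBBB), so the per-marker signal fraction *hex/(fam+hex)*
   forms up to five clusters.  A one-dimensional Gaussian mixture with
   order-constrained means is fitted per marker on the
   arcsine-square-root scale; BIC selects the number of classes, and a
   sample is called only when its class posterior reaches 0.6
   (`DosageMixtureModel(...).fit()` → results object with calls,
   per-marker fits and a `summary()` table).
3. **Marker statistics** per marker from the dosage-class tally
   *n₀…n₄* over called samples:
   - MA = Σ_d (4−d)·n_d / (4·n_called) — mean A-allele frequency,
   - OH = (n₁+n₂+n₃)/n_called — observed heterozygosity,
   - PIC = 1 − Σ_g f_g² — gene diversity over the five dosage classes
     (maximum 0.8 at five equal classes).
4. **Fingerprints and identity**: loci with PIC > 0.6 form the
   fingerprint; pairwise Euclidean distances on the dosage vectors plus
   a UPGMA dendrogram detect synonyms (distance 0, identical
   fingerprints) and homonyms (same name, positive distance).
5. **Synthetic data** for every stage, with ground truth: tetraploid
   Hardy–Weinberg dosage matrices (Binomial(4, q)), noisy two-channel
   signals, toy cohort VCFs with planted perfect SNPs, and planted
   synonym/homonym cases.

## Worked example

The package ships the published 71-marker potato PARMS-SNP dosage-class
table as a reference panel.  Expanding it to a per-sample matrix and
running the statistics stage:

```python
from tetrafinger.datasets import panel_counts, expand_counts_to_matrix
from tetrafinger.marker_stats import (compute_marker_stats,
                                      summarize_markers, drop_monomorphic)
from tetrafinger.fingerprint_identity import select_fingerprint_loci

matrix = expand_counts_to_matrix(panel_counts(), drop_empty_samples=True)
stats = compute_marker_stats(matrix)
print(stats.loc[["StSNP54", "StSNP24", "StSNP63"],
                ["n0", "n1", "n2", "n3", "n4", "n_called",
                 "MA", "OH", "PIC"]].round(4))
```

```
          n0  n1  n2  n3  n4  n_called      MA      OH     PIC
marker
StSNP54    4  11  52  71  39       177  0.3164  0.7571  0.6999
StSNP24   13  64  77  29   7       190  0.5618  0.8947  0.6930
StSNP63  190   0   0   0   0       190  1.0000  0.0000  0.0000
```

StSNP54 is a highly informative marker (PIC ≈ 0.70: its 177 called
samples spread over all five dosage classes), while StSNP63 is
monomorphic (every sample nulliplex, PIC 0) and carries no identification
power.  The cohort summary and fingerprint panel:

```python
s = summarize_markers(stats)
print(f"mean MA {s['MA']['mean']:.4f}  mean OH {s['OH']['mean']:.4f}  "
      f"mean PIC {s['PIC']['mean']:.4f}")
reduced = drop_monomorphic(matrix, stats)
loci = select_fingerprint_loci(stats.loc[reduced.columns], 0.6)
print(reduced.shape, len(loci))
```

```
mean MA 0.6720  mean OH 0.6010  mean PIC 0.4309
(190, 69) 21
```

Two monomorphic markers are dropped, leaving a 190-sample × 69-marker
panel, and 21 loci pass the PIC > 0.6 fingerprint threshold.

A shell-level run over a simulated cohort:

```bash
tetrafinger simulate vcf --samples 50 --sites 50 --perfect 5 \
    --violators 3 --seed 1 --out-dir sim/
tetrafinger run --vcf sim/cohort.vcf --out-dir discovery/
# -> "5 perfect-SNP candidates -> discovery/"
```

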