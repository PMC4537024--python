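# tamdereg

Classification of nuclear-receptor target genes from paired transcriptome
and cistrome data, built around the deregulation of PPARβ/δ targets in
tumor-associated macrophages (TAMs) from ovarian carcinoma ascites.

## The problem

PPARβ/δ is a fatty-acid–activated transcription factor. In monocyte-derived
macrophages (MDMs) its direct target genes respond cleanly to synthetic
ligands: induced by an agonist, repressed by inverse agonists. In TAMs the
same genes sit at an elevated baseline and barely respond to the agonist —
they are *refractory* — plausibly because ascites supplies saturating
endogenous fatty-acid agonists (linoleic acid at ~180 µM against a 0.75 µM
IC₅₀). `tamdereg` implements the full desk-side analysis that establishes
this picture:

1. **Expression filtering** — a gene is considered expressed if FPKM ≥ 0.3
   and ≥ 50 deduplicated tags jointly in at least one sample; optional
   quantile normalization across all samples.
2. **Ligand-response classification** — per-donor pairwise
   log₂FC = log₂((FPKM_treated + 0.1)/(FPKM_control + 0.1)); a gene is a
   direct target if |log₂FC| ≥ 0.7 in ⌈0.8·n⌉ of n donor pairs (4-of-5 at
   n = 5) in any of three comparisons: agonist vs solvent (up), inverse
   agonist vs solvent (down), agonist vs inverse agonist (up).
3. **Cistrome integration** — ChIP peaks pass with ≥ 30 tags and a
   library-normalized fold change over IgG ≥ 2; enrichment sites must be
   reproducible in ≥ 2 of 3 samples (single-linkage overlap merge); a gene
   is peak-associated if its TSS lies within 50 kb of a site.
4. **TAM deregulation** — up-in-TAM *in vivo*: log₂ of the pseudocounted
   ratio of median FPKM (10 ex vivo TAMs vs 5 MDM controls) ≥ 1 with an
   equal-variance t-test on log₂(FPKM+0.1) at Benjamini–Hochberg
   FDR ≤ 0.05. Refractory: an MDM-inducible gene whose TAM induction misses
   the log₂FC ≥ 1 threshold or stays below 50 % of the MDM fold change.
5. **Lipidomics** — calibration-line quantification helpers and mass→molar
   conversion (µg/ml → µM via c·1000/M), with fold-over-IC₅₀ comparisons.
6. **Survival** — Kaplan–Meier curves, logrank test with
   HR = (O_A/E_A)/(O_B/E_B), and the "auto select best cutoff" expression
   scan (with its anti-conservatism made explicit).
7. **Synthetic data** — a seeded generator that plants all of this
   structure (targets, TAM-up subset, refractory subset, peaks, survival
   effects) so every stage is testable against known truth without any
   download.

The package is a library: import it from Python, or start from the short
scripts in `examples/`.

## Worked example

`python examples/classify_synthetic_cohort.py` simulates the default study
design (2000 genes, 195 planted direct targets, 5 MDM donors, 10 TAM
patients, 3 cultured-TAM donors, 3 ChIP samples) and runs the full
classification:

```
genes simulated:            2000
expressed (FPKM/tag filter): 1974
ligand-regulated targets:   197
  with TAM ChIP peak:       95
up in TAM (ex vivo):        54
  also refractory:          32
up in cultured TAM:         48
recovery of planted targets: precision 0.990, recall 1.000
```

197 genes are called ligand-regulated against 195 planted (precision 0.99,
recall 1.0); the TAM-upregulated (54), refractory (32) and peak-associated
(95) sets recover the planted nested structure. The other examples cover
peak-to-gene assignment on a hand-built locus, the lipid panel conversions,
and the survival cutoff scan.

## Layout

- `src/tamdereg/types.py` — domain types (samples, studies, peaks, reports)
- `src/tamdereg/io.py` — TSV/BED-plus/GTF readers and writers
- `src/tamdereg/preprocess.py` — quantile normalization, expression filter, FPKM
- `src/tamdereg/ligand.py` — pairwise log-fold-changes, consistency rules
- `src/tamdereg/cistrome.py` — peak filtering, reproducibility, TSS windows
- `src/tamdereg/dereg.py` — TAM deregulation, t-test/FDR, refractory calls
- `src/tamdereg/lipidomics.py` — calibration and unit conversion
- `src/tamdereg/survival.py` — KM, logrank, best-cutoff scan
- `src/tamdereg/synth.py` — ground-truth generators
- `src/tamdereg/pipeline.py` — end-to-end orchestration
- `docs/methods.md` — model, parameter and design notes
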