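# Methods

## The classification model

The pipeline is deliberately threshold-based rather than model-based: the
question it answers is membership in a handful of biologically defined
sets (expressed; ligand-regulated; peak-associated; up-in-TAM;
refractory), each set defined by explicit cutoffs on fold changes and
counts, not by a fitted differential-expression model. No dispersion
estimation or shrinkage is performed anywhere; where a distributional test
is used (the TAM-vs-MDM comparison) it is a classical pooled-variance
two-sided t-test with Benjamini–Hochberg correction.

### Expression filter

A gene is expressed if at least one sample satisfies FPKM ≥ 0.3 **and**
tag count ≥ 50 *jointly*. The joint reading (rather than the two
thresholds being satisfiable in different samples) is the stricter and, we
judge, the intended one: 50 tags in a sample where FPKM < 0.3 is evidence
of length/depth, not of expression. Filtering happens on raw FPKM/tags;
quantile normalization, when requested, is applied afterwards. Quantile
normalization maps each column's order statistics to the across-sample
mean of order statistics; ties receive the mean of the reference values at
their tied ranks, which makes the transform independent of row order. The
transform is idempotent on tie-free data; with ties the second application
can shift values slightly because the tie-averaged column changes the
reference.

### Ligand response

Fold changes are computed pairwise within donor —
log₂((FPKM_t + 0.1)/(FPKM_c + 0.1)) — never across donors, so donor-level
expression offsets cancel exactly. The pseudocount of 0.1 bounds the fold
change of near-zero baselines while perturbing values above the 0.3
expression floor by < 15 %. The consistency rule requires the threshold
(0.7 log₂ units, inclusive) in ⌈0.8·n⌉ of n donor pairs, which
reproduces the 4-of-5 rule at n = 5 and generalizes conservatively to
other donor counts. A gene is ligand-regulated if it passes in any of the
three comparisons (agonist up vs solvent; inverse agonist down vs solvent;
agonist up vs inverse agonist), with the two inverse agonists (ST247,
PT-S264) combined by union. Cultured-TAM ligand response uses a different
published convention, kept as such: median pairwise log₂FC ≥ 1.0
(inclusive) plus the expression floor.

### Cistrome

Peak filtering: tags ≥ 30 and a library-size-normalized fold change over
IgG ≥ 2, with one pseudo-tag added to the IgG side only (prevents division
by zero; conservative for the ChIP side). Reproducibility: single-linkage
merge of intervals overlapping by ≥ 1 bp (half-open; adjacency does not
merge), retained at ≥ 2 distinct supporting samples. Gene assignment: TSS
within 50 kb (inclusive) of a consensus span, distance measured to the
nearest retained base of the interval (peak summits are not available in
the input format), strand-ignored. "Close to" a site is read as the same
50-kb rule, not a second threshold.

### TAM deregulation and refractory calls

Up-in-TAM *in vivo* compares median FPKM of the 10 ex vivo TAM samples
with the 5 MDM solvent controls (log₂ pseudocounted ratio ≥ 1), gated by
an equal-variance t-test on log₂(FPKM + 0.1) at BH FDR ≤ 0.05 computed
across the target set. The log scale is a deliberate choice: the
equal-variance assumption is untenable on raw FPKM. The degenerate
zero-variance cases return p = 1 (equal means) or p = 0 (unequal), logged.
The FDR gate is configurable off (`apply_fdr=False`); the default applies
it. An alternative reading of the *in vivo* threshold as 0.7 log₂ units
exists in the source material; 1.0 is the default and the value is a
parameter.

Up-in-TAM *in vitro* compares a single cultured-TAM solvent sample against
every MDM solvent sample, requiring log₂FC ≥ 0.7 **and** an absolute
margin of ≥ 0.5 FPKM against each. This rule uses the raw ratio (no
pseudocount): its worked convention is plain arithmetic, and the absolute
margin already guards the low end.

Refractory: among MDM-agonist-inducible genes, a gene is refractory if its
TAM median log₂FC is below the TAM induction threshold (1.0) *or* its TAM
fold induction is below half the MDM fold induction. The two branches are
a union, so a strongly MDM-induced gene can be refractory even while
nominally passing the TAM threshold.

## The synthetic-data generator

The generator is the package's test bed, not a cohort simulator; its job
is recoverability under known truth. It emulates:

- per-gene baseline log₂ FPKM ~ N(3, 2); per-donor offsets ~ N(0, 0.2);
  per-sample log-normal noise (σ = 0.3 log₂ units);
- multiplicative agonist induction on planted targets
  (log₂FC ~ N(3.0, 0.5)) and inverse-agonist repression at −0.5× that
  magnitude, giving the union structure of the three comparisons;
- TAM baseline elevation (+2 log₂ units) on the planted TAM-up subset and
  attenuated TAM induction (×0.2 fold) on the refractory subset, nested
  refractory ⊆ TAM-up ⊆ targets;
- tag counts negative-binomial around the exact FPKM-implied mean
  (mean = FPKM·length·libsize/10⁹), with the returned FPKM matrix
  recomputed from the counts so the two matrices satisfy the FPKM relation
  exactly;
- ChIP peaks of 400 bp placed uniformly within ±50 kb of planted-target
  TSSs, present in ≥ 2 of 3 samples, plus sample-unique decoys placed
  > 50 kb from every TSS (removed by the reproducibility rule by
  construction);
- survival cohorts with exponential event times, a hazard multiplier on
  the top fraction of a normal expression marker, and independent
  exponential censoring.

The NB dispersion parameter (default 0.01) models *technical* count-level
overdispersion only. Biological variability between donors and samples is
already modeled explicitly in log space (donor offsets plus σ = 0.3
noise); using a biological-replicate-scale dispersion (~0.1) in the count
layer as well would double-count that variance and is not what the layered
model means. Default set sizes (195/54/32/95) mirror the published counts
so that a default run prints numbers on the published scale; effect sizes
(induction log₂FC mean 3, TAM baseline shift 2) are chosen as the
qualitative magnitudes the study reports (tens-fold induction of the
strongest targets).

What the generator does *not* emulate — and hence what passing tests do
not certify about real data: GC/length biases, batch effects, correlated
genes, isoform-level ambiguity, mappability artifacts in peaks, or
informative censoring. The generator's clean multiplicative structure is
exactly recoverable in the zero-noise limit, which the tests use as an
identity check, not as a claim about biological attainability.

## Survival analysis

The KM estimator and medians come from the product-limit formula (median =
first time S(t) ≤ 0.5, undefined if never reached). The logrank statistic
is the classical O−E tabulation over risk sets with the hypergeometric
variance and (N−d)/(N−1) tie correction; the hazard ratio is the O/E
ratio form, flagged unstable when a group has no events. The best-cutoff
scan evaluates every distinct expression value between the 10th and 90th
percentiles (high = strictly greater than the cutoff) and returns the
split minimizing the *nominal* p-value, as the referenced class of web
tools does. The scan's anti-conservatism is a property, not a bug to fix
silently: on null data its rejection rate at p < 0.05 is far above 5 %
(the acceptance suite measures ≈ 0.45 at n = 200), and the package logs a
warning every time the scan runs. External-cohort numbers (the published
TCGA split and hazard ratio) depend on data this package does not ship and
are not recomputed; the survival module is validated by calibration and
inflation properties instead.

## Numerical and problem-size choices

- BH q-values via the standard step-up implementation; the test suite
  checks it against a literal enumeration of the definition (exhaustive on
  short lists over a 0.01 p-grid, sampled up to length 8 — the full grid
  at length 8 is combinatorially out of reach and adds nothing).
- Interval arithmetic is 0-based half-open everywhere; GTF input (1-based
  closed) is converted on read, TSS = gene start on "+", end−1 on "−".
- Recovery statistics pool 20 simulated cohorts of 2000 genes; survival
  calibration uses 1000 cohorts of n = 200. These sizes give Monte-Carlo
  standard errors well inside the asserted margins while keeping a full
  run in tens of seconds.
- Ties at the survival cutoff go to the low group (high = strictly
  greater); ties in expression ranks during quantile normalization are
  averaged; even-length medians are the mean of the middle two.

## Known limitations

- The classification is only as calibrated as its thresholds; the package
  reproduces a published rule set rather than estimating error rates from
  data.
- `filter_expressed` rejects missing values rather than imputing;
  upstream quantifiers are expected to emit complete matrices.
- The in vitro comparison keys on a single cultured-TAM sample by design;
  with several candidates the first in metadata order is used unless one
  is named explicitly.
- IC₅₀ values for minor ligands (15-HETE, prostacyclin) are
  literature-dependent and must be supplied by the user; only linoleic
  acid's 0.75 µM value ships with the panel.
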