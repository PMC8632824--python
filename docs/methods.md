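# Methods

## Study design being emulated

The pipeline targets a field drought experiment in *Sorghum bicolor*: two
genotypes (RTx430, pre-flowering drought tolerant; BTx642, post-flowering
"stay-green"), three irrigation regimes — watered control; pre-flowering
drought with watering withheld during weeks 3–8 followed by re-watering
and recovery through week 17; post-flowering drought with watering
withheld during weeks 10–17 — 17 weekly samplings and three replicate
plots per genotype × condition, analyzed per tissue (leaf or root). The
full factorial therefore has 2 × 3 × 17 × 3 = 306 samples per tissue.

## Synthetic data generator

### Count model

Counts are negative binomial with gene-wise mean and a common dispersion
φ (variance μ + φμ²; default φ = 0.1, a typical bulk RNA-seq value for
field-grown biological replicates). Per-gene baselines are log2-uniform
over (2, 9), i.e. mean counts of roughly 4–512, spanning the range where
log-scale inference is noise-limited to where it is effect-limited.
Per-sample library-size factors are log-uniform over (0.7, 1.4), so
upper-quartile normalization has real work to do.

### Planted drought responses

A fraction `frac_responsive` (default 0.1) of genes receives a smooth
log2 fold-change trajectory relative to control, with a random sign per
gene and peak magnitude exactly `effect_size_log2` (default 2.0). Two
archetypes are planted:

* **Sustained responders** (`frac_sustained` = 0.2 of the responsive set)
  follow a flattened-sine bump across the whole stress window — weeks 3–8
  for the pre-flowering regime (continuing at half amplitude,
  `recovery_fraction` = 0.5, through the recovery weeks 9–17) and weeks
  10–17 for the post-flowering regime. These emulate the core cell-wall
  drought program: genes whose expression is persistently shifted for the
  duration of the stress, and hence carry a large time-averaged fold
  change.
* **Transient responders** (the remaining 80%) pulse for
  `transient_width` = 3 weeks at a random position inside the stress
  window. They are readily detected by the time-course F-test (the
  trajectory peaks at the same ±2 log2 units) but carry a small
  time-averaged fold change, as most general stress-responsive expression
  does.

This two-class structure is what makes HVG selection a meaningful
recovery problem: the HVG definition ranks by time-averaged fold change,
so the sustained program should populate the top/bottom tails while the
transient background fills the middle of the eligible set.

### Annotations and chemistry

Cell-wall GO annotation (the four terms GO:0009832, GO:0071555,
GO:0071554, GO:0042546; 1–2 terms per annotated gene) is assigned to
exactly `round_half_up(frac_cellwall_annotated × n)` genes. The
annotation budget is drawn first from the sustained responders
(`cellwall_responsive_overlap` = 1.0 by default — the planted cell-wall
program *is* the sustained program), then from non-responsive genes, so
the annotated/responsive overlap is exactly controlled. A small disjoint
curated list and a gene-family label (used by the functional classifier)
complete the annotation set.

Chemistry assays are simulated per analyte × genotype × condition × week
as replicate triplets drawn log-normally (mean-preserving, replicate CV
default 10%) around `control_mean × (1 + effect/100)`. The default
planted effects mirror the reported week-7 pre-flowering leaf matrix
monosaccharide increases — +62% rhamnose, +33% arabinose, +62% glucose,
+37% galacturonic acid — as realistic effect sizes.

### What the generator does not emulate

No read-level data, alignment or gene-length effects; no batch or plot
(block) structure beyond independent replicates; no genotype-specific
response amplitudes (both genotypes share each gene's trajectory); no
count-level correlation between genes; no chromatogram traces (signals
arrive already integrated). Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated under its stated
assumptions — not that those assumptions exhaust real field data.

## Analysis pipeline

### Preprocessing

Genes with mean count below `min_mean` (default 1, configurable) are
dropped. Upper-quartile factors are the 75th percentile of each sample's
*nonzero* counts (linear interpolation), rescaled to geometric mean 1 so
normalized values stay on the counts scale; the log matrix is
log2(normalized + 1). The pseudocount of 1 biases fold changes toward
zero for genes with single-digit counts; this attenuation is visible in
power at the low end of the expression range.

### Time-course model

The spline basis is a natural cubic (truncated-power) basis with
`spline_df` = 4 degrees of freedom, knots at quantiles of the distinct
weeks, boundary knots at the extremes, columns centered with constants
frozen at construction; `df` = 1 degenerates to a centered linear term.
For sub-period fits the df is capped at (number of distinct weeks − 1).
The full model per gene, condition pair and genotype is
`1 + f(week) + condition + condition:f(week)` on log2 values, fit by
least squares simultaneously for all genes; the null model omits the
condition terms, giving q = df + 1 condition parameters. A singular or
saturated design yields NA fits (logged), which propagate to NA p-values
and are excluded from eligibility with a count in the log.

Least squares on log-transformed normalized counts (rather than a
count-likelihood GLM) keeps the empirical-Bayes moderation exact and is
the standard linear-model route for time-course microarray/RNA-seq
designs; the null calibration tests confirm it is well calibrated under
the generator's NB noise.

### Variance moderation and test

Residual variances are shrunk toward a prior: s̃² = (d₀s₀² + d s²)/(d₀+d),
with (d₀, s₀²) estimated by moment matching on log s² — the empirical
variance of log s² is matched to trigamma(d/2) + trigamma(d₀/2) and
inverted by Newton iteration; when the empirical variance does not exceed
trigamma(d/2) the prior df is capped at 10⁶ (full shrinkage). With fewer
than 10 genes moderation is skipped (d₀ = 0). The moderated
F = ((RSS₀−RSS₁)/q)/s̃² is referred to F(q, d₀+d). Genes with zero
numerator and zero moderated variance (no signal, no noise) are defined
as F = 0, p = 1.

### HVG selection

Per condition and period, the genotypes' raw p-values are combined by
Fisher's method; zero p-values are clamped to the smallest positive
float with a warning. BH adjustment is applied within each
condition × period p-value vector (the "family" is one condition and one
tissue, matching one unique p-value per gene per drought condition per
sample type). Eligibility is adjusted p < 0.05; ranking is by the
genotype-specific overall lfc.

The literal overall-fold-change expression sign(mean L) × (mean L)
evaluates to |mean L| and admits no bottom tail; the signed mean is
therefore the default ranking statistic (`lfc_mode="signed_mean"`), with
the literal absolute form available as `lfc_mode="as_printed"`. The
top/bottom cut is ceil(0.05 × n_eligible) per end; ties break by smaller
adjusted p, then lexical gene id; when 2·ceil exceeds n the bottom list
is truncated so no gene appears in both ends. Eight lists are built
(2 conditions × 2 genotypes full-course, plus pre-flowering
drought-weeks-only and recovery-weeks-only × 2 genotypes) and merged as a
tagged union.

### Cell-wall restriction and summary

GO matching is by exact term id against the four cell-wall terms plus
curated membership — no ontology-graph propagation by default, since the
filter is defined by four specific terms (an optional OBO-based
propagation mode exists). Functional classification uses a
family → category table (glycosyltransferases/synthases → biosynthesis;
expansins, XTHs, peroxidases, pectin-active enzymes, glycosyl
hydrolases → modification; wall-associated/receptor-like
kinases → signaling); unmapped genes default to "modification" with a
flag. The summary counts genes per tissue × treatment × category,
extracts L at the focus weeks 7 and 14 (the representative pre- and
post-flowering time points), and labels the main trend from the mean L
over the condition's stress window with a ±0.25 log2 "no change" band
(configurable; there is no canonical threshold).

### Chemistry

Calibration is unweighted OLS through the standard points (≥3 distinct
levels; R² < 0.99 warns). Back-calculated levels outside 0.5×–2× the
standard range are flagged extrapolated; negative levels clamp to zero
with a flag. %ABSL = 100 × (A280/(ε·path)) × volume/mass with
ε = 18.19509 g⁻¹ L cm⁻¹ (commelinid average); path length and extract
volume are required inputs. Saccharification nets out the T0 reading and
floors negative net release at zero. Contrasts are two-sided
pooled-variance Student t-tests (the replicate design is three pooled
plots per group; Welch would cost df with no protection at n = 3), BH
adjusted within a tissue × genotype × week family across analytes, with
the dual decision rule: raw p < 0.05 and BH survival at FDR 0.25, both
reported. The replicate outlier screen (off by default in the pipeline)
removes at most one replicate whose deviation from the others' mean
exceeds k = 4 of their SD, never below two survivors, with all removals
logged; the rule is declared policy, not a recovered criterion.

## Numerical choices and degenerate inputs

* Size-factor rescaling uses the geometric mean; an all-zero sample is an
  error naming the sample.
* RSS nesting violations from round-off are clamped (RSS₀ ≥ RSS₁
  enforced); F is nonnegative by construction.
* Trigamma inversion: Newton with positivity safeguard, relative
  tolerance 1e-10.
* Zero pooled variance in a t-test: equal means → (t=0, p=1); unequal
  means → (±inf, 0) flagged "degenerate".
* All seeded draws go through `numpy.random.default_rng`; a config plus
  one integer seed reproduces every output byte-for-byte (the manifest
  deliberately records no timestamps).

## Problem sizes

The test suite and the acceptance script run the generator at its default
2000 genes × 306 samples for the calibration and recovery studies, 5000
analytes × 2 weeks (10,000 contrasts) for the chemistry null, and smaller
matrices (120–300 genes) for structural and CLI checks; these sizes give
stable estimates of rejection rates and recall while the full run stays
in the tens of seconds on one core.

## Known limitations

* The moderated-F p-values are parametric; no permutation null is run by
  default (a residual-permutation mode would be the natural extension).
* The genotype contrast is exposed (`timecourse.genotype_contrast`) but
  sits outside the HVG path and is only smoke-tested.
* Recovery-window lists are small under the default generator (the
  attenuated recovery response yields few eligible genes), so the merged
  set is dominated by the full-course and drought-window lists.
* Percent-change reporting breaks down when the control mean is zero
  (reported as NaN).
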