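# Methods

This note records the statistical models, parameter choices, and numerical
conventions behind `crisprai-screen`, and what the synthetic-data tests do
and do not establish about real data.

## Single-cell guide assignment

Cells pass QC only if every comparison holds strictly: genes detected
> 200 and < `max_genes`, transcriptome UMIs < `max_umis`, mitochondrial
percentage < 10, guides with nonzero reads > 20, guide UMIs > 50. The upper
gene/UMI bounds vary per capture in practice; the defaults (6,900 genes,
51,000 UMIs) sit at the midpoints of the typical per-capture ranges
(5,500–8,300 and 27,000–75,000) and should be tuned per capture. The
removal tally attributes each cell to the *first* filter it fails, in the
order min_genes, max_genes, max_umis, max_pct_mito, min_guides_detected,
min_guide_umis.

A guide is called when its share of the cell's guide reads reaches the
capture-appropriate fraction — 20% for single-capture and 10% for
double-capture cells. The comparison is `>=`; the boundary direction is a
convention of this package and is pinned by tests. The fraction rule is the
sole caller here (no upstream feature-calling step), which makes the
assignment self-contained and exactly reproducible.

Detection error rates: FNR is the fraction of double-capture cells with
exactly one called guide; FPR the fraction of single-capture cells with two.
Denominators include only assignable cells (1–2 calls). Cells with zero
guide reads or more than two calls carry no usable evidence about
single-versus-double detection, so they are excluded; with a different
denominator convention the estimates shift by the (small) share of such
cells, which is why the convention is stated here and in the docstring.

## Differential expression

Counts are normalized as `ln(1 + count / cell_total × 1e4)`. Per gene, a
logistic regression predicting group membership (perturbed vs NTC) from the
gene's normalized expression plus batch indicator covariates is compared to
the covariate-only null by a likelihood-ratio test (χ², 1 df). The null
model does not depend on the gene and is fit once per comparison. Fits use
an L2 ridge of 1e-6 — negligible for well-conditioned genes, but it keeps
coefficients finite under complete separation; fits whose coefficient
magnitude exceeds 15 are flagged as ridge-dominated. The fold-change
estimate is `log2((mean(expm1(x)) + 1)_A / (mean(expm1(x)) + 1)_B)`, the
common single-cell convention; the +1 pseudocount shrinks magnitudes for
weakly expressed genes, which is why planted two-fold effects are recovered
at ≈ 0.97 rather than exactly 1.0 (tests allow ±0.3). DE gene sets use
`p_adj < 0.05` and `|log2FC| > 0.5`, both strict.

**Compositional caveat.** Because expression is normalized per cell, strong
planted up-regulation raises a genotype's total counts and pushes every
other gene's *relative* abundance down. In simulations where planted genes
are a large share of the transcriptome, background genes acquire genuine
negative log2FCs in the perturbed genotypes and enter the DE (and hence
mode-classified) sets. This is a property of normalization-based DE, not of
the simulator; it largely cancels in the observed-minus-expected difference
because singles and doubles shift together.

## Regulatory modes

With `d = observed − expected` (expected = sum of the single log2FCs):
synergy when `|d| > 0.1` and (|observed| > |expected| or opposite signs);
buffer when `|d| > 0.7` and |observed| < |expected|; additive otherwise. A
zero value matches either sign. The buffer threshold is read as a magnitude
(|d|), with the directional qualifier carrying the sign information; a
brute-force truth-table test over (observed, expected) ∈ [−2, 2]² at step
0.05 pins the implementation. Only genes significant in at least one of the
three DE sets are classified. The synergy:buffer ratio is undefined (NaN)
when no buffer genes exist.

Module scores bin genes into 25 expression-average bins and, per set gene,
draw up to 100 control genes from its bin excluding set genes. Draws are
without replacement within a draw (capped at bin size): this makes the
one-bin, exhaustive-control case reduce exactly to
`mean(set) − mean(complement)`, which the tests verify against a direct
computation. The score is mean(set) − mean(controls, with multiplicity)
per cell, seeded and reproducible.

## Sort-screen scoring

Per replicate, guide pairs with ≤ 300 raw reads summed over all collected
populations are dropped (the unsorted sample counts toward the sum when
present; a flag excludes it). Normalization is `log2(1 + CPM)` — the
pseudocount is applied after CPM scaling, one of the two readings the
convention permits; it is documented and tested in closed form. Log2FC is
taken against the cytokine-negative (NEG) population, and z-scores are
`(lfc − mean(NTC)) / sd(NTC)` with sample s.d. (n−1), computed independently
per replicate and per screen. By construction the NTC set has mean 0 and
s.d. 1 exactly; z is invariant under any positive affine transform applied
uniformly to the log2FCs. Outlier-guide removal is a user-supplied exclusion
list only, never automatic.

Perturbation strength is reported three ways (difference to the TSS log2FC,
percent of TSS log2FC, and difference to the average NTC log2FC) rather
than conflating them; percent-of-TSS is undefined when the TSS log2FC is 0.

## Genetic-interaction scores

Expected double z = sum of the single z's (averaging guides per
element/direction). Per replicate, observed is regressed on expected by OLS
with intercept (not orthogonal regression — matching the standard linear
model default), and the GI score is the residual. Method 1 flags pairs
outside 1 s.d. from the residual mean and requires the flag in **all**
replicates. Method 2 standardizes residuals, reports a Shapiro–Wilk
normality p (advisory: a warning, not a gate), and computes
`p = 2·(1 − Φ(|residual_z|))`, uncorrected, flagged at p < 0.05. The
two-sided tail is used because significant interactions of both signs must
be detectable; a one-sided lower tail could not produce positive-residual
hits. Consensus requires method 1 **and** method-2 flags in every replicate
(the stringent reading; an any-replicate mode is exposed). Degenerate case:
when all residuals are identical (s.d. 0), method 1 issues a warning with
no flags and method 2 sets residual_z = 0, p = 1 — so the exact-additivity
limit yields slope 1, intercept 0, R² 1 and zero hits.

Gatekeeper detection formalizes the hierarchy readout: an element (other
than the TSS, whose dominance is the expected baseline) is called a
gatekeeper when its single-perturbation z is at least 50% of the
same-direction TSS single z, and at least half of its bidirectional pairs
with opposing partners (partner single z of opposite sign) have a pair z
following the element's own sign. Both thresholds are configuration values.
Strength here is computed on the z scale; because z is NTC-centered this
tracks the log2FC ratio closely.

## Epigenomic signal

Coordinates are 0-based half-open (BED). The mean signal over an element is
the base-pair-weighted average of bedGraph values; uncovered bases count as
0 by default (a flag averages covered bases only). Occupancy uses
`log2(signal + 0.01)`; a gene is bound iff any of its elements — the
promoter window (TSS ± 1 kb, clipped at the chromosome start) or an
annotated enhancer — exceeds 5 strictly. ATAC tracks are normalized per
sample by `(raw + 1e-4) / chrom_total × 1e6`, where the chromosome total is
the sum of value × interval width on the normalization chromosome (chr4 by
default); the pseudocount is added to the raw value before division.

## Synthetic data

The simulators emulate the statistical structure the analyses assume, with
every effect planted and echoed back:

* **Perturb-seq counts** are negative binomial with variance
  `μ + μ²·dispersion` (dispersion 0.3), mean
  `baseline × 2^lfc × batch × size`, log-normal library-size variation
  (s.d. 0.3), and multiplicative batch factors. The canonical planted truth
  uses four genotypes and plants five genes per mode at baseline mean 20
  counts (well-detected targets): additive (+0.8/−0.6, double = sum),
  synergy (+0.5/+0.2, double 1.4, d = +0.7), buffer (+1.0/+1.0, double 0.9,
  d = −1.1); background genes draw log-normal means around ~2 counts.
* **Guide capture**: total guide UMIs per cell ~ Poisson(500)+1; 2% of
  reads are ambient, spread Dirichlet-multinomially over all library
  guides. The ambient level of real captures is not well characterized —
  2% is a stand-in and a visible knob (`GuideNoise.ambient_frac`). Dual
  cassettes split reads Dirichlet(10, 10). The dropout degrader suppresses
  one guide of a double to 4% of reads (below the 10% threshold) with
  probability FNR, and inflates an ambient guide of a single to 30% (above
  20%) with probability FPR.
* **Sort screens**: each pair's latent expression is
  `x ~ N(Σβ + ε, 1)`; a hard threshold at 1.0 defines the positive gate
  (mirroring FACS gating; a logistic gate is a config option away in the
  latent scale). Population counts are multinomial over pairs with
  probabilities ∝ pool fraction × gate probability, drawn at 1e6 reads per
  population — the analytic ("cell-equivalent") form of per-cell Bernoulli
  draws. The standard pool is 13 elements (TSS + 12 enhancers) × {a, i}: 26
  singles, 156 bidirectional a×i doubles, 18 NTC pairs = 200 pairs,
  3 replicates. Because read-sampling noise at this depth is small, planted
  β of order 1 latent unit produce large |z| — sign and calibration
  behavior, not the absolute z scale, are what the tests exercise.
* **Signal tracks** are piecewise constant: bound elements at level 40,
  background at 0.5 (log2 ≈ 5.32 vs −0.97, straddling the threshold of 5 by
  more than two-fold), optional Gaussian bin noise, 50-bp bins.

Child seeds derive from the master seed by
`child = (seed × 1,000,003 + k) mod 2³¹`, so adding a replicate or matrix
never perturbs earlier streams; identical configuration and seed give
byte-identical outputs.

**What the simulations do not capture:** UMI collisions, doublets,
cell-to-cell transcriptional covariance, guide-efficacy heterogeneity
within an element, read-level errors, overdispersion of sort counts beyond
multinomial (e.g. biological replicate variance from finite sorted cells),
and real chromatin-track autocorrelation. Passing tests therefore establish
the correctness and calibration of the *computations* under their stated
models, not the wet-lab operating characteristics of any particular screen.

## Problem sizes

Defaults in tests and the acceptance script: 200-pair screens × 3
replicates × 50 seeds for GI calibration/recovery; 500 cells per genotype
(× 20 seeds for mode recovery); 1,000 genes × 2 × 300 cells for DE null
calibration; 2,000 cells per capture type for FNR/FPR estimation; 1,000
random intervals for the signal-aggregation oracle. These sizes give
binomial/Monte-Carlo standard errors comfortably inside the asserted
tolerances.

## Configuration

All thresholds live in one flat YAML-backed schema (`config.py`) with the
defaults named throughout this note; unknown keys are rejected and the full
effective configuration is echoed into every run directory. Exit codes:
0 success, 2 validation error, 3 runtime/data error.
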