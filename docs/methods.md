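# Methods

## Scope and design

cubkit implements the standard codon-usage-bias workflow for panels of
protein-coding sequences: per-gene indices (RSCU, Wright's ENC,
positional GC, third-base composition), the three bias-source
diagnostics (ENC-plot, PR2 plot, neutrality regression), optimal-codon
determination from ENC-extreme gene groups, three-level association of
bias with expression, and RSCU-based genome clustering.  The package is
organised as one module per pipeline stage with a thin `cubkit` CLI on
top; all tabular state lives in pandas DataFrames and all heavy metric
computation is vectorised over a genes × 64 codon count matrix whose
column order (alphabetical codons) is fixed so outputs are reproducible
byte for byte.

## Quality control

CDS shorter than 300 bp are removed outright (short sequences give
unstable indices); the threshold applies to the raw length and is
strict (`< 300` removed, 300 kept).  Sequences whose length is not a
multiple of three have the trailing 1–2 bases trimmed and are flagged;
sequences with an in-frame internal stop are flagged but retained,
since stop codons never enter any statistic.  `strict=True` turns both
flags into rejections.  These conventions are configurable because
upstream annotation pipelines differ in how they emit partial CDS.

## Index conventions

- **RSCU** is computed per amino acid with at least one occurrence;
  amino acids absent from a gene or pool are *masked* (NaN), not set to
  zero, so downstream pooling and ΔRSCU cannot mistake absence for
  avoidance.  For every present amino acid the RSCU values sum to its
  degeneracy (checked to 1e-9 in the tests).
- **ENC** follows the classic estimator: per degenerate amino acid with
  occurrence count n ≥ 2, `F̂ = (n Σ p̂² − 1)/(n − 1)`; amino acids with
  F̂ ≤ 0 or n < 2 are excluded from their class mean; six-fold families
  (Leu, Ser, Arg) are kept whole.  `ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ +
  3/F̄₆`, with F̄₃ imputed as (F̄₂ + F̄₄)/2 when Ile is unusable and ENC
  undefined when a 2-, 4- or 6-fold class mean is missing.  Values
  above 61 are capped; the floor of 20 is asserted, never clamped.
- **Positional GC** is computed over all sense codons (stops excluded;
  Met/Trp included, since their first two positions are informative);
  GC is the mean of GC1–GC3 and GC12 the mean of GC1–GC2.
  **A3/T3/G3/C3 and GC3s** are counted over synonymous codons only
  (Met, Trp, stops excluded), which also feeds the PR2 coordinates —
  single-codon amino acids would otherwise distort the parity test.
  These are raw counts, not codonW's "A3s"-style rescaled fractions; a
  codonW-compatibility mode is out of scope.

## Diagnostics

The ENC-plot deviation is reported as `ENC_exp − ENC_obs`, so positive
deviations mean the gene lies below the expected curve
`ENC_exp(s) = 2 + s + 29/(s² + (1 − s)²)` (selection-consistent).  Note
the curve's exact maximum sits at s ≈ 0.502 (value 60.50003), not 0.5 —
the linear term breaks the symmetry; the identity
`ENC_exp(s) − s = ENC_exp(1 − s) − (1 − s)` is exact.

The neutrality fit is ordinary least squares of GC12 on GC3 with the
Pearson correlation and its two-sided p-value (Student t, n − 2 df).  A
constant GC3 regressor or fewer than three genes is an error, not a
silent NaN.

## Optimal codons

Genes are ranked by ENC; each tail receives ⌈fraction · n⌉ genes
(default fraction 0.05), with ties at the cutoff broken by gene id so
group membership is deterministic.  RSCU is computed on *pooled* counts
per tail (the convention of codonW-style workflows), and
ΔRSCU = RSCU(low-ENC pool) − RSCU(high-ENC pool).  A codon is optimal
when RSCU > 1 **in the high-bias pool** and ΔRSCU > 0.08, both strict.
The orientation of ΔRSCU and the pool on which the RSCU condition is
evaluated flip calls if changed, so both are stated here prominently;
the whole-dataset pooled RSCU is used only for the over-/under-
representation flags (1.6 / 0.6).

The 0.08 threshold is an absolute difference, so its noise floor is set
by pool size: tails must pool enough codons that the sampling standard
deviation of ΔRSCU is well below 0.08.  The recovery tests therefore
use panels of ~12 000 genes (tails of 600 genes × ~500 codons), which
is the regime the method is designed for — genome-scale inputs, where
tails of a few hundred to a few thousand genes are typical.  On small
inputs (hundreds of genes) ΔRSCU calls include sampling noise, which is
visible in the CLI demo outputs.

## Expression association

Tiers are high (RPKM > 10), medium (1 < RPKM ≤ 10), low (0 < RPKM ≤ 1),
excluded (RPKM = 0), on the per-gene mean across tissues.  Within each
tier genes split into strong/weak bias at the within-tier median ENC by
default (a fixed ENC threshold is available; the choice of split is a
genuine free parameter of this analysis style).  RPKM is
log10(x + 1)-transformed before Welch t-tests to tame the heavy right
tail; raw-scale testing is available.  The Welch statistic uses the
Satterthwaite degrees of freedom; t > 0 always means the first-named
group (strong bias, G/C-dominant, G/C-preferring) has the higher mean.
Raw p-values carry the 0.05 significance flags, matching common
practice in this literature; Benjamini–Hochberg-adjusted values are
reported alongside for readers who prefer them.  Dominant third bases
tie-break in the fixed order T > A > G > C; within-amino-acid preferred
codons are the per-gene count argmax, and tied genes are excluded for
that amino acid (counted in the output).

## Clustering

Genomes are embedded as pooled 59-dimensional RSCU vectors (alphabetical
codon order), compared by Euclidean distance and clustered
agglomeratively; average linkage is the default because no linkage is
canonical for this analysis, with single/complete/ward exposed.  The
Newick export places each merge's children at half the merge height, so
leaf-to-root depth equals half the final merge distance.  Flat clusters
at k are obtained by applying the first n − k merges directly, which
yields exactly k clusters regardless of tied heights.  The
Robinson–Foulds utility compares the RSCU dendrogram against a
user-supplied reference tree; it is a comparison aid, not a
phylogenetic inference — RSCU clustering is known to disagree with
sequence phylogenies.

## Synthetic data generator

The generator is deliberately a *statistical* emulator, not an
evolutionary simulator: no phylogeny, indels or recombination.  Each
gene draws amino acids i.i.d. from a 20-letter frequency vector
(default: typical globular-protein composition) and codons from a
two-part rule:

1. with probability β (bias strength) the amino acid's designated
   preferred codon is used outright (default preferred map: A/U-ending
   codons, the preference typical of plant genomes);
2. otherwise codon weights are gc3 for G/C-ending and 1 − gc3 for
   A/T-ending codons within the amino acid, where gc3 is the gene's
   GC3 target (Uniform over `gc3_range`).  At gc3 = 0.5 this is exactly
   uniform, so β interpolates between uniform usage (ENC → 61) and
   single-codon usage (ENC → 20).

GC12 is controlled by exponentially tilting the amino-acid frequencies
so the expected positions-1+2 GC equals a per-gene target
`λ · E[GC3] + (1 − λ) · gc12_base + ε`, with ε ~ N(0, gc12_noise) and
E[GC3] the gene's expected *realized* third-position GC including the
invariant G contributed by Met, Trp and the start codon.  This makes
the coupling λ (`gc3_coupling`) the true neutrality-plot slope on the
scale the diagnostic measures.  Two residual biases remain and are
quantified in the tests: errors-in-variables attenuation of order
var(GC3 noise)/var(GC3), negligible for genes ≳ 1000 codons, and the
tilt's mild distortion of amino-acid composition.

Expression is log-normal: each gene draws a latent tier
(high/medium/low/silent, default probabilities 0.30/0.35/0.25/0.10)
with mean log10 RPKM 1.8/0.5/−0.7 and s.d. 0.25, plus γ · β
(`expression_coupling`, default 0.5 ≈ a 0.5 s.d. shift across the
default β range); tissues are replicates with s.d. 0.1 and silent genes
are exactly 0.  Genes that cross tier boundaries because of the γ · β
term stay where their realized RPKM puts them, which attenuates
within-tier coupling in mixed-tier panels — the directional power tests
therefore use single-tier panels, where the spec'd effect is cleanly
recoverable.

Every generated CDS starts with ATG, ends with one stop codon, contains
no internal stop and is ≥ 300 bp, so whole panels pass QC untouched.
Genome panels for clustering perturb the preferred-codon map per group
(each amino acid's preference switches with probability `divergence`),
giving a planted partition with tunable separation.

What passing tests on these data do **not** show: robustness to real
annotation noise (frame errors, chimeric CDS), to non-i.i.d. amino-acid
composition (domain structure), to expression measures other than RPKM,
or to genomes whose bias violates the single-preferred-codon-per-amino-
acid structure.

## Problem sizes and numerical choices

Test and acceptance runs use panel sizes chosen to put sampling noise
well below each decision threshold: 12 000 genes × 400–600 codons for
ΔRSCU recovery and null calls (tail pools ≈ 3 × 10⁵ codons, ΔRSCU noise
s.d. ≈ 0.02 against the 0.08 threshold), 2 000 genes for slope recovery,
300 × 1500–2500 codons for the λ-extreme checks, 500 simulations × 200
genes for null calibration of the expression tests.  Tolerances: RSCU
normalization and oracle equivalence at 1e-9; OLS against the
closed-form oracle at 1e-10; the analytic ENC-curve anchors at 1e-12.
All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical configuration and seed reproduce
every output byte for byte.

## Known limitations

- codonW-compatible "A3s/T3s/G3s/C3s" denominators are not implemented;
  values are raw synonymous third-base counts.
- CAI, Fop, tAI and other reference-set indices are out of scope.
- The ENC exclusion rules (F̂ ≤ 0, occurrence < 2) are one defensible
  reading of the classic estimator; published tools differ in edge
  cases, so per-gene ENC can differ slightly from codonW on short
  genes.
- Expression-defined (rather than ENC-defined) reference sets for
  optimal codons are not provided.
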