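# Methods

## Data model and expression scale

The central object is a cells × genes matrix over a fixed assay panel.
Raw cycle-threshold (Ct) values from the instrument are inverted,
`x = max(0, ceiling − Ct)` with `ceiling = 35` cycles (configurable), giving
a log2-like abundance scale on which 0 encodes non-detection. Missing
reactions, no-call sentinels (e.g. 999) and any Ct at or above the ceiling
are treated uniformly as non-detected; the instrument's failed-reaction
encoding is not standardized, so a single conservative rule is applied.
Values are keyed by cell id and gene symbol throughout — row/column order
is preserved from the input files but never used for identification.
Expression tables round-trip through TSV bit-identically (floats serialized
by `repr`, parsed in round-trip mode); the Ct-encoded path preserves
detection exactly and magnitudes to one floating-point rounding step, since
`ceiling − (ceiling − x)` is not representable-exact for every `x`.

## Quality control

1. **Housekeeping prescreen.** Cells with zero housekeeping expression
   (*Gapdh* by default) are dropped ("absent"). Over the expressing cells a
   95% acceptance interval is computed; cells outside are dropped
   ("outlier"). The interval is the normal coverage interval
   `mean ± z(0.975)·SD` (sample SD, n−1), closed at its endpoints; a
   quantile interval ([2.5th, 97.5th] percentiles) is available as
   `method="quantile"`. A confidence interval *for the mean* would shrink
   with √n and reject nearly every cell, so the coverage reading is the one
   consistent with use as an outlier screen. The screen is pooled across
   collection batches. Note that mean±z·SD trimming is not idempotent in
   general — removing tails shrinks the SD, so re-screening can remove
   boundary cells; with outliers well separated from the cohort it converges
   in one pass. Beads are never subject to this screen.
2. **Identity gate.** Sorted cells of a population that lack their defining
   transcript (e.g. an Hcrt/Ox-sorted cell with no *Hcrt* signal) are
   removed — mislabeled or misidentified captures.
3. **Bead report.** Sorted fluorescent beads carry no cell; any detected
   gene in a bead measures ambient-transcript contamination of the FACS
   droplet. The report lists detected genes per bead; it drops nothing.

## Differential detection

Inference is purely presence/absence: a gene is detected in a cell iff its
inverted-Ct value is positive. For two populations, each gene yields a 2×2
table (detected/not × population). The two-sided Fisher exact p-value sums
hypergeometric point probabilities not exceeding the observed table's with
a `1 + 1e-7` relative tie tolerance — the convention of the mainstream
statistical environments, which makes published tables reproducible digit
for digit. The sum is accumulated in log space (`logsumexp`), keeping
p-values near 1e-50 accurate; when every admissible table qualifies, the
value is exactly 1. Benjamini–Hochberg adjustment runs over the full
48-gene panel (housekeeping and markers included), and significance is
called at FDR q = 0.05. The ranking statistic is the absolute proportional
difference in percent, rounded half-away-from-zero to the nearest integer
(the printed-table convention). Ties in the ranked table break by ascending
adjusted p, then symbol. The between-batch test applies the identical
machinery to the two collection batches within one population.

## Multivariate structure

- **z-scoring** standardizes each gene to mean 0, sample SD 1 (n−1);
  zero-variance genes map to all-zero columns and are reported.
- **PCA** is the SVD of the centered matrix; variance fractions are
  normalized squared singular values (dividing by n or n−1 changes
  numerator and denominator identically, so fractions are unaffected).
  Sign convention: each loading column's largest-magnitude entry is made
  positive, so reported poles are stable across platforms. PCA input is
  z-scored expression.
- **Hierarchical clustering** supports Ward (default) and complete linkage
  on Euclidean distances (the phrase "Ward's method with complete linkage"
  is internally contradictory — Ward *is* a linkage — so both are
  implemented and the 2-cut purity is reported for both). Clustering input
  defaults to raw inverted-Ct values rather than z-scores: z-scoring is a
  PCA preprocessing step, and on presence/absence-dominated panels it
  inflates rare genes (a detection in a gene with prevalence p scores
  z ≈ √((1−p)/p)), letting sporadic rare-gene detections misroute outlier
  cells. Purity of a k-cut is the summed per-cluster majority-label count
  over n.
- **Coverage ellipses** in a 2-D score plane use the sample mean and
  covariance with the χ²(2 df) quantile at the coverage level (5.991 at
  95%).

## Power analysis

For group sizes (n₁, n₂) and true detection probabilities (p₁, p₂), each
Monte Carlo replicate draws k₁ ~ Binomial(n₁, p₁), k₂ ~ Binomial(n₂, p₂)
and applies the two-sided Fisher test; power is the fraction of replicates
with p < α (strict inequality — the discrete test is conservative, so the
null rejection rate sits below α). Defaults mirror the study design:
n₁ = 69, n₂ = 89, α = 0.05, 1000 replicates, effect levels
Δ ∈ {0, 0.15, 0.25, 0.35}. The study states the effect levels but not the
baselines; the grid defaults to baselines {0.1, 0.3, 0.5}. Each grid cell
runs on its own substream derived deterministically from the master seed
and the cell's (baseline, Δ) coordinates, so cells are independent and
individually reproducible. An exact companion enumerates all (k₁, k₂)
outcomes with binomial weights; at the study's sizes the exact power at
Δ = 0.35 (0.30 vs 0.65) is 99.2%, comfortably above the 90% adequacy
threshold quoted for moderate effects.

## Colocalization, fidelity, cross-dataset comparison

Dual-label FISH/IHC quantification arrives as counts (image segmentation
and the ≥5-puncta scoring happen upstream): percentage colocalization is
100·(double-positive)/(reference-positive), rounded half-away-from-zero to
one decimal. Reporter fidelity: specificity = % of reporter-positive cells
immunoreactive for the defining peptide, penetrance = % of immunoreactive
cells that are reporter-positive. Population-average expression includes
non-detected zeros by default (the average then reflects prevalence ×
magnitude; a detected-only mean is available). Cross-dataset comparison
uses Spearman rank correlation over the intersection of gene keys with
mid-rank ties; the two-sided p-value uses the t-approximation for n ≥ 10
and exact permutation enumeration below (the n = 10 boundary avoids
enumerating 3.6M permutations for negligible gain). Pairwise Pearson
correlation matrices within a population are computed on continuous
inverted-Ct values by default (binary option available); zero-variance
genes are flagged undefined rather than silently set.

The firing-signature classifier labels a recorded neuron H-type if its
latency to first spike after a 1 s hyperpolarizing step strictly exceeds
100 ms, else D-type; features arrive pre-extracted from electrophysiology.

## Synthetic data generator

The generator emulates the study design, not any particular realized
dataset: populations of n = 89 (MCH) and n = 69 (Hcrt/Ox) cells; per gene
and population, detection is Bernoulli with probabilities defaulting to the
published empirical proportions; detected magnitudes are Normal(μ, σ)
truncated to (0, ceiling]. The default magnitude model is
abundance-coupled, μ = 6 + 12·p (σ = 3), so prevalent transcripts are
abundant and rarely detected transcripts sit near the detection floor —
the canonical dropout–abundance relationship of single-cell qPCR, and the
feature that keeps trace detections of a marker in the "wrong" population
at trace magnitude. With a flat μ the generated populations are *not*
perfectly separable by clustering (sporadic cross-population marker
detections at full abundance create ambiguous cells), which real data of
this kind are. μ and σ accept scalars or per-gene/per-population tables.
Each population splits into two equal collection batches; planted batch
effects shift one gene's detection probability in the second batch.
Each preparation contributes 8 all-zero beads whose genes light up
independently with probability 0.005 at magnitude Uniform(1, 5), mimicking
trace ambient transcripts. Everything is drawn from one `numpy`
Generator, so output is bit-identical given (spec, seed).

What the generator does **not** model: gene–gene correlation beyond what
population identity induces (detections are conditionally independent),
amplification bias, probe efficiencies, cell-size/quality covariation, and
batch effects in magnitude. Tests passing on synthetic data therefore
demonstrate correctness of the statistical machinery under the study's
sampling model, not robustness to these real-data features.

Two statistical cautions on recovery tests, reflected in how they are
asserted. First, regenerating detection from the published proportions and
re-testing flags the strongly differential genes every time, but genes at
the FDR boundary (e.g. adjusted p ≈ 0.009 or ≈ 0.1) legitimately flip under
binomial resampling; the recovery test therefore requires every strongly
differential gene (published adjusted p ≤ 1e-4) in every seed and a mean
Jaccard overlap ≥ 0.8 with the published significant set over 20 seeds.
Second, checking ~60 non-degenerate per-gene detection fractions against
central 99% binomial regions is a 60-test family — all-inside holds only
~73% of the time for a correct generator — so the check allows up to 3
exceedances (the 99.9% family quantile).

## Problem sizes used

Simulation-backed tests run at the study's own scale (158 cells + 16 beads
× 48 genes) over 20 seeds for structure recovery, 50 seeds for planted
batch-effect recovery, and 1000–2000 Monte Carlo replicates per power
estimate; the exact-enumeration power oracle is exercised at group sizes
≤ 25. Fisher p-values are memoized on the table counts, which makes the
replicated simulations cheap.

## Known limitations

- The housekeeping screen assumes approximately normal housekeeping
  expression among sound cells; heavy-tailed cohorts are better served by
  the quantile option.
- The exact test's conservativeness means null rejection rates can sit well
  below α for small groups; power estimates inherit this.
- Printed-table reproduction depends on the point-probability two-sided
  convention; environments using the "double one-sided" convention will
  differ on asymmetric tables.
- The generator's independence assumptions make it unsuitable for testing
  methods whose validity hinges on gene–gene correlation structure (the
  Pearson-matrix stage is exercised with explicitly planted correlations in
  the tests instead).
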