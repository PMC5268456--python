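# Methods

## The stability screen

A gene's expression stability is summarised by one number: the trimmed
max/min fold change across all samples,
`FC_k = ((k+1)-th largest value) / ((k+1)-th smallest value)`, computed
per gene on a strictly positive matrix. The statistic is deliberately a
range ratio rather than a variance-type measure: the screening question
is whether a gene *ever* departs from its level across organs, ages and
sexes, not how much it wiggles on average. Its weakness — extreme
sensitivity to single aberrant measurements — is addressed by the trim:
at `k = 1` the single highest and single lowest value of each gene are
discarded before the ratio is formed, so one corrupted cell per gene
cannot move the statistic beyond the gene's untrimmed range.

Properties the implementation guarantees (and the test suite asserts):

- `FC_k >= 1`, with equality exactly for genes constant after trimming;
- invariance under rescaling the whole matrix (normalisation-unit free);
- `FC_k` non-increasing in `k` for every gene;
- corrupting the current extreme value (×10⁶ or ÷10⁶) leaves `FC_1`
  bitwise unchanged, and corrupting *any* single cell keeps
  `FC_1 ≤ FC_0(original)`. Note the stronger claim sometimes stated for
  trimmed ranges — that any single-cell corruption leaves the trimmed
  ratio exactly unchanged — is false (corrupting an interior value
  promotes the old maximum into the trimmed comparison); the bounded
  version above is the property that actually protects the SEG calls.

Ties: duplicated values occupy distinct sorted positions. The SEG
threshold comparison is inclusive (`fc <= threshold`). An asymmetric trim
(`k_high`, `k_low`) is exposed for grids that remove unequal numbers of
high and low samples. Fold changes are stored in linear space; plots and
histograms use log10 (the observed dynamic range spans ~10 decades).

## Preprocessing

Four rules, applied in this order: drop unannotated transcripts (empty
`gene_id` is the explicit sentinel for "no gene ID"); drop transcripts
that are zero in every sample; resolve redundant transcripts of a gene to
the one with the highest arithmetic mean across samples (ties broken by
file order; means computed *before* zero substitution, since redundancy
resolution precedes substitution); replace remaining zeros with the
global minimum non-zero value of the matrix.

The substitution minimum is global, not per gene or per sample: a single
substitution constant keeps the fold change well defined for near-silent
genes without inventing per-gene pseudo-counts. A per-gene variant was
considered and rejected as under-determined (a gene with one non-zero
sample would substitute its own value and appear spuriously stable).
The pipeline is idempotent, never touches the sample columns, and its
report satisfies `n_output = n_input − n_unannotated − n_all_zero −
n_redundant` by construction.

## Enrichment and association statistics

- **Fisher's exact test**, two-tailed by the point-probability
  convention: the p-value sums the probabilities of all tables with the
  observed margins whose point probability does not exceed the observed
  one. The implementation is `scipy.stats.fisher_exact`; the test suite
  verifies it against an exact-rational brute-force enumeration,
  exhaustively for all tables with both row margins ≤ 20 (~53 000
  tables) and on 2000 random tables with margins up to 60 — a problem
  size chosen to keep the property suite fast while covering the
  regime the analyses use.
- **Odds ratio**: the raw cross-product `(Na·Nd)/(Nb·Nc)` with no
  continuity correction (zero cells yield 0 / +inf sentinels and a
  warning). The 95% CI is Woolf's logit interval with z = 1.96; on the
  published knockout counts (15, 1, 421, 920) this reproduces
  OR 32.78, CI (4.32, 248.97) to printed precision, which is how the CI
  method was identified.
- **FDR**: Benjamini–Hochberg step-up (via statsmodels), the default
  reading of "control the FDR at 5%" when no procedure is named; the
  enrichment universe is all genes surviving preprocessing, not the
  union of the gene sets.
- **Rank comparison**: Mann–Whitney U with midranks. Exact null
  distribution when `n_group · n_rest ≤ 10⁴` and the scores are
  tie-free, otherwise the normal approximation with tie and continuity
  correction. Sidedness is explicit (`two-sided`, `group-lower`,
  `group-higher`); directional claims ("SEG homologs rank lower") use
  the one-sided variant, but the two-sided p is always computable.

## The synthetic study generator

The generator emulates the statistical structure the analysis assumes,
at the level the analysis consumes (a normalised FPKM-like matrix — it
is *not* a read-count simulator):

- **Design**: organs × ages × sexes × replicates, default
  11 × 4 × 2 × 4 = 352 samples; `sex_specific_organs=True` makes testis
  male-only and uterus female-only, giving the 320-sample layout of the
  real study this emulates.
- **Baselines** are log-uniform over 10⁻¹–10⁴ (the dynamic range of
  bulk FPKM data).
- **Stable genes**: multiplicative log-normal noise, clipped to a
  half-width of `½·ln(0.96 · stable_fc_max)` so the realized max/min
  ratio of the whole row — hence every trimmed ratio — is guaranteed
  below `stable_fc_max` (default 3.0). Clipping trades distributional
  realism for *exact* ground truth: recall/precision tests can demand
  1.0 rather than "with high probability".
- **Variable genes**: the same noise plus an organ- or age-driven
  multiplicative shift with floor `variable_fc_min · stable_fc_max`, so
  the trimmed fold change provably exceeds `variable_fc_min`
  (default 10) at any trim up to 4 (the smallest shifted stratum has 16
  samples). Both bounds are re-checked at generation and violation is a
  hard error.
- **Artifacts**: with probability `outlier_rate` per transcript
  (default 1%), one random cell is multiplied or divided by 10⁶
  (recorded in the truth object); low cells of non-stable transcripts
  are zeroed with probability `zero_rate` (default 1%). Zeroing exempts
  stable rows: after substitution by the global minimum non-zero value
  a zeroed cell would fall outside the clipped noise band and silently
  void the planted bound the separability invariant asserts.
- **Removable rows**: unannotated transcripts (empty gene_id) and
  redundant duplicates (a 0.1–0.8× scaled copy of an existing row
  sharing its gene_id, hence strictly lower mean).
- **Validation tables**: homolog map (configurable coverage, default
  0.8), Bernoulli lethality flags with a planted odds ratio (default 30
  over a 31% baseline), and normal scores on a damage-index-like scale
  (mean 4.35, sd 2.0, stable-homolog shift −1.1, floored at 0.01).

Default class sizes (100 stable, 4600 variable, 150 unannotated, 150
redundant ≈ 5000 transcripts) keep the stable fraction at ~2%, the same
order as the ~1% observed in real multi-organ data, while the total stays
desk-sized. All outputs are pure functions of (design, seed).

**What passing tests do and do not show.** The generator's classes are
separable by construction, its noise is bounded, and its artifacts are
injected one-per-gene at most. Perfect recovery on this data therefore
demonstrates the *mechanics* of the statistic (trimming absorbs exactly
the artifacts it is designed for; thresholds act as specified), not that
real tissues contain a cleanly separable stable class: in real data the
fold-change distribution is continuous and the SEG count varies with the
cutoff, which is why the threshold/trim grid exists.

## Problem sizes and numerical choices

Calibration tests use 1000 replicates (enrichment null: 20 sets × 1000
collections; rank-test null: groups of 20 in 200 scored genes, exact
p-values); the planted rank-shift detection uses 5000 scored genes. The
whole suite runs in under a minute on one CPU; the acceptance script in
seconds. Histogram bins default to decade bins over 1–10¹⁰ with overflow
clipped into the last bin; medians use the midpoint convention. All
file formats are plain TSV/GMT with `.` decimals; identifiers are
case-sensitive throughout (symbol case distinguishes species).

## Known limitations

- The statistic ranks genes by range ratio only; genes stable in 319 of
  320 samples but with two aberrant cells at the same tail escape a
  trim-1 screen. The grid (trims up to 4) is the mitigation, not a fix.
- The global zero-substitution constant couples a gene's minimum to the
  most extreme low value anywhere in the matrix; genes with many zeros
  get fold changes dominated by the substitution constant.
- The generator plants at most one outlier per transcript; real
  artifact processes can hit several cells of the same gene.
- Enrichment p-values are unconditional Fisher tests over possibly
  overlapping sets; no set-overlap correction is attempted.
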