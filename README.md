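# segscan

Identification of **stably expressed genes (SEGs)** — genes whose
expression stays nearly constant across organs, ages and sexes — from a
gene × sample expression matrix (FPKM-like units), with the downstream
statistics used to validate such a gene list: gene-set enrichment,
knockout-lethality association, and cross-species rank comparisons.

Stable reference genes matter wherever expression is quantified against an
endogenous control (qPCR normalisation, cross-tissue comparisons), and
classical "housekeeping" lists turn out to be surprisingly variable when
examined across many organs. `segscan` implements a deliberately simple,
robust screening statistic for expression stability and the companion
analyses, plus a synthetic-study generator so the whole pipeline is
testable without any external download.

## The statistic

For a gene with strictly positive expression values \(x_1,\dots,x_n\)
across all samples, the **trimmed max/min fold change** at trim level
\(k\) is

```
FC_k = x_((n-k)) / x_((k+1))
```

the ratio of the \((k{+}1)\)-th largest to the \((k{+}1)\)-th smallest
order statistic — i.e. the \(k\) most extreme values on each side are
discarded before forming the max/min ratio. At the default \(k=1\),
`FC = fpkm_max−1 / fpkm_min−1` (second-highest over second-lowest), which
makes the ratio immune to a single aberrant measurement per gene. Genes
with `FC ≤ 4.0` at trim 1 are called SEGs in the headline analysis; a
threshold {3,4,5} × trim {0..4} grid maps the robustness of the calls.

Before the statistic is computed, the matrix is reduced by four rules:
transcripts without a gene annotation are dropped, transcripts that are
zero in every sample are dropped, redundant transcripts of a gene are
resolved to the one with the highest mean, and remaining zeros are
replaced by the global minimum non-zero value so the ratio stays finite.

Validation statistics: Fisher's exact test (two-tailed, point-probability
convention) with Benjamini–Hochberg FDR over gene sets; the 2×2
cross-product odds ratio `OR = (Na·Nd)/(Nb·Nc)` with a Woolf (logit) 95%
CI `exp(ln OR ± 1.96·√(1/Na+1/Nb+1/Nc+1/Nd))`; and the Mann–Whitney U
test for rank shifts of SEG homologs in an external score (expression
stability in another species, or a mutational damage index).

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
320-sample design (11 organs × 4 ages × 2 sexes × 4 replicates, testis
male-only and uterus female-only) with 100 planted stable genes among
5000 transcripts:

```
$ python analysis/03_stability.py --seed 1
SEGs at FC<=4, trim 1: 100 of 4700 genes (2.1%)
planted-truth recall 1.000, precision 1.000
SEG counts (rows: FC cutoff 3/4/5, cols: trim 0..4):
trim_k       0    1    2    3    4
threshold
3.0        100  100  100  100  100
4.0        100  100  100  100  100
5.0        100  100  100  100  100
fold-change range 2.87 .. 2.75e+13, median 741.2

$ python analysis/05_association.py --seed 1
published knockout-lethality table (15, 1, 421, 920): OR=32.78 (95% CI 4.32-248.97), p=3.84e-07
  lethal fraction: SEG homologs 94%, others 31%
87 of 100 SEGs have homologs (13 unmapped)
synthetic lethality table (82, 5, 1158, 2536): OR=35.9 (planted 30.0), p=1.8e-34
damage-score rank test (group-lower): U=118098, p=1.16e-05; medians 3.64 vs 4.42
```

Reading this: the trimmed statistic recovers exactly the planted stable
class (recall = precision = 1) at every threshold/trim regime; most genes
are anything but stable (median fold change ~741); the published
knockout-lethality 2×2 table reproduces to printed precision (knocking
out a SEG homolog is lethal in 94% of lines vs 31% for other genes,
OR ≈ 33); and on synthetic validation tables the pipeline recovers a
planted lethality odds ratio of 30 and detects the planted downward shift
of SEG-homolog damage scores.

The same stages are available as a CLI
(`segscan simulate|preprocess|stability|stability-grid|enrich|assoc-2x2|rank-compare|run`),
e.g. `segscan assoc-2x2 --counts 15,1,421,920`.

## Layout

- `src/segscan/` — the library: `matrix_io` (TSV/GMT/two-column formats),
  `preprocess`, `stability`, `enrichment`, `association`, `synthetic`
  (study generator with planted truth), `pipeline` + `cli`.
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `tests/` — pytest suite with brute-force oracles for every statistic.
- `docs/methods.md` — model, assumptions, parameter choices, limitations.
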