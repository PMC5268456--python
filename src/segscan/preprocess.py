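"""Transcript-selection rules that reduce a transcript-by-sample matrix to a
unique-gene-by-sample matrix suitable for stability analysis.

The pipeline applies, in order: (1) drop transcripts without a gene
annotation, (2) drop transcripts that are zero in every sample, (3) for each
gene keep only the transcript with the highest mean expression, (4) replace
all remaining zeros with the global minimum non-zero value of the matrix so
that max/min fold changes stay finite.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .matrix_io import ExpressionMatrix, GeneTable

__all__ = [
    "PreprocessReport",
    "filter_unannotated",
    "filter_all_zero",
    "resolve_redundant",
    "substitute_zeros",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class PreprocessReport:
    """Row accounting for a preprocessing run.

    ``substitution_value`` is the global minimum non-zero expression value
    used to replace zeros, or ``None`` if the matrix contained no zeros.
    """

    n_input_transcripts: int
    n_removed_no_gene_id: int
    n_removed_all_zero: int
    n_removed_redundant: int
    n_output_genes: int
    substitution_value: float | None

    def __post_init__(self) -> None:
        expected = (
            self.n_input_transcripts
            - self.n_removed_no_gene_id
            - self.n_removed_all_zero
            - self.n_removed_redundant
        )
        if self.n_output_genes != expected:
            raise ValueError(
                f"inconsistent report: {self.n_output_genes} output genes but "
                f"counts imply {expected}"
            )
        if self.substitution_value is not None and self.substitution_value <= 0:
            raise ValueError("substitution_value must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _check_annotated(matrix: ExpressionMatrix, genes: GeneTable) -> None:
    for transcript in matrix.gene_ids:
        if transcript not in genes:
            raise KeyError(f"transcript {transcript!r} absent from gene table")


def filter_unannotated(matrix: ExpressionMatrix, genes: GeneTable) -> ExpressionMatrix:
    """Drop rows whose transcript has no gene annotation (empty gene_id)."""
    _check_annotated(matrix, genes)
    keep = [t for t in matrix.gene_ids if genes.gene_id(t) != ""]
    return matrix.select_genes(keep)


def filter_all_zero(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop rows whose expression is exactly zero in every sample."""
    values = matrix.values
    keep_mask = (values != 0).any(axis=1)
    keep = [g for g, k in zip(matrix.gene_ids, keep_mask) if k]
    return matrix.select_genes(keep)


def resolve_redundant(matrix: ExpressionMatrix, genes: GeneTable) -> ExpressionMatrix:
    """Keep, for each gene, the single transcript with the highest mean
    expression across all samples; re-key surviving rows by gene_id.

    Ties on the mean are broken by first occurrence in row order. The mean
    is computed on the matrix as given (i.e. before zero substitution).
    """
    _check_annotated(matrix, genes)
    transcripts = matrix.gene_ids
    for transcript in transcripts:
        if genes.gene_id(transcript) == "":
            raise ValueError(
                f"transcript {transcript!r} is unannotated; run "
                "filter_unannotated first"
            )
    means = matrix.values.mean(axis=1)
    best: dict[str, tuple[int, float]] = {}
    for i, transcript in enumerate(transcripts):
        gene = genes.gene_id(transcript)
        if gene not in best or means[i] > best[gene][1]:
            best[gene] = (i, means[i])
    keep_rows = sorted(i for i, _ in best.values())
    kept_transcripts = [transcripts[i] for i in keep_rows]
    reduced = matrix.select_genes(kept_transcripts)
    return reduced.relabel_genes(genes.gene_id(t) for t in kept_transcripts)


def substitute_zeros(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, float]:
    """Replace every zero cell with the global minimum non-zero value of the
    matrix; returns the new matrix and the substitution value used."""
    values = matrix.values
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("matrix is all zero; no substitution value exists")
    substitution = float(nonzero.min())
    out = values.copy()
    out[out == 0] = substitution
    return matrix.with_values(out), substitution


def preprocess_pipeline(
    matrix: ExpressionMatrix, genes: GeneTable
) -> tuple[ExpressionMatrix, PreprocessReport]:
    """Run the four transcript-selection rules in order and account for every
    removed row. The sample (column) set is never modified."""
    n_input = matrix.n_genes
    annotated = filter_unannotated(matrix, genes)
    n_no_gene = n_input - annotated.n_genes
    expressed = filter_all_zero(annotated)
    n_all_zero = annotated.n_genes - expressed.n_genes
    unique = resolve_redundant(expressed, genes)
    n_redundant = expressed.n_genes - unique.n_genes
    if unique.n_genes == 0:
        report = PreprocessReport(n_input, n_no_gene, n_all_zero, n_redundant, 0, None)
        return unique, report
    had_zeros = bool((unique.values == 0).any())
    substituted, value = substitute_zeros(unique)
    report = PreprocessReport(
        n_input_transcripts=n_input,
        n_removed_no_gene_id=n_no_gene,
        n_removed_all_zero=n_all_zero,
        n_removed_redundant=n_redundant,
        n_output_genes=substituted.n_genes,
        substitution_value=value if had_zeros else None,
    )
    return substituted, report
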