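import numpy as np
import pytest

import segscan as sg
from conftest import make_matrix


def gene_table(pairs):
    return sg.GeneTable(dict(pairs))


class TestFilterUnannotated:
    def test_drops_rows_with_empty_gene_id(self):
        matrix = make_matrix(np.ones((5, 3)), gene_ids=[f"t{i}" for i in range(5)])
        genes = gene_table({"t0": "g0", "t1": "", "t2": "g2", "t3": "", "t4": "g4"})
        out = sg.filter_unannotated(matrix, genes)
        assert out.gene_ids == ["t0", "t2", "t4"]

    def test_identity_when_all_annotated(self, small_matrix):
        genes = gene_table({g: f"gene_{g}" for g in small_matrix.gene_ids})
        out = sg.filter_unannotated(small_matrix, genes)
        assert out.equals(small_matrix)

    def test_all_unannotated_gives_empty_matrix(self, small_matrix):
        genes = gene_table({g: "" for g in small_matrix.gene_ids})
        out = sg.filter_unannotated(small_matrix, genes)
        assert out.n_genes == 0
        assert out.sample_ids == small_matrix.sample_ids

    def test_missing_transcript_names_it(self, small_matrix):
        genes = gene_table({"g1": "x"})
        with pytest.raises(KeyError, match="g2"):
            sg.filter_unannotated(small_matrix, genes)


class TestFilterAllZero:
    def test_drops_all_zero_row(self):
        matrix = make_matrix([[0, 0], [1, 0], [0, 2]])
        out = sg.filter_all_zero(matrix)
        assert out.gene_ids == ["g2", "g3"]

    def test_single_non_zero_value_is_retained(self):
        matrix = make_matrix([[0, 0, 0.001], [0, 0, 0]])
        out = sg.filter_all_zero(matrix)
        assert out.gene_ids == ["g1"]


class TestResolveRedundant:
    def test_keeps_highest_mean_transcript(self):
        matrix = make_matrix([[5.0, 5.0], [7.0, 7.0]], gene_ids=["t1", "t2"])
        genes = gene_table({"t1": "GeneA", "t2": "GeneA"})
        out = sg.resolve_redundant(matrix, genes)
        assert out.gene_ids == ["GeneA"]
        np.testing.assert_array_equal(out.values, [[7.0, 7.0]])

    def test_single_transcript_kept_and_rekeyed(self):
        matrix = make_matrix([[1.0, 2.0]], gene_ids=["t1"])
        out = sg.resolve_redundant(matrix, gene_table({"t1": "GeneA"}))
        assert out.gene_ids == ["GeneA"]
        np.testing.assert_array_equal(out.values, matrix.values)

    def test_tie_broken_by_first_occurrence(self):
        matrix = make_matrix([[2.0, 4.0], [4.0, 2.0]], gene_ids=["t1", "t2"])
        genes = gene_table({"t1": "GeneA", "t2": "GeneA"})
        out = sg.resolve_redundant(matrix, genes)
        np.testing.assert_array_equal(out.values, [[2.0, 4.0]])

    def test_matches_brute_force_argmax_on_random_fixture(self):
        rng = np.random.default_rng(42)
        n_transcripts, n_genes = 30, 10
        values = rng.uniform(0, 100, size=(n_transcripts, 12))
        tids = [f"t{i:02d}" for i in range(n_transcripts)]
        assignment = {t: f"gene{rng.integers(n_genes)}" for t in tids}
        matrix = make_matrix(values, gene_ids=tids)
        out = sg.resolve_redundant(matrix, gene_table(assignment))

        # independent brute-force scan over every transcript of every gene
        expected = {}
        for i, t in enumerate(tids):
            g = assignment[t]
            mean = values[i].mean()
            if g not in expected or mean > expected[g][0]:
                expected[g] = (mean, i)
        assert set(out.gene_ids) == set(expected)
        for g in out.gene_ids:
            np.testing.assert_array_equal(out.row(g), values[expected[g][1]])

    def test_unannotated_row_rejected(self):
        matrix = make_matrix([[1.0, 2.0]], gene_ids=["t1"])
        with pytest.raises(ValueError, match="unannotated"):
            sg.resolve_redundant(matrix, gene_table({"t1": ""}))


class TestSubstituteZeros:
    def test_documented_example(self):
        matrix = make_matrix([[0.0, 2.0], [4.0, 0.5]])
        out, value = sg.substitute_zeros(matrix)
        assert value == 0.5
        np.testing.assert_array_equal(out.values, [[0.5, 2.0], [4.0, 0.5]])

    def test_no_zeros_means_identity(self, small_matrix):
        out, value = sg.substitute_zeros(small_matrix)
        assert out.equals(small_matrix)
        assert value == small_matrix.values.min()

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="all zero"):
            sg.substitute_zeros(make_matrix([[0.0, 0.0]]))

    def test_output_min_equals_input_min_nonzero(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0.01, 10, size=(40, 15))
        values[rng.random(values.shape) < 0.1] = 0.0
        matrix = make_matrix(values)
        out, value = sg.substitute_zeros(matrix)
        assert value == values[values > 0].min()
        assert out.values.min() == value
        # non-zero cells untouched
        mask = values > 0
        np.testing.assert_array_equal(out.values[mask], values[mask])


class TestPipeline:
    def test_report_counts_match_generated_composition(self, small_study):
        design, matrix, _, genes, _ = small_study
        clean, report = sg.preprocess_pipeline(matrix, genes)
        assert report.n_input_transcripts == design.n_transcripts
        assert report.n_removed_no_gene_id == design.n_unannotated
        assert report.n_removed_redundant == design.n_redundant_extra
        assert report.n_output_genes == clean.n_genes
        assert (
            report.n_output_genes
            == report.n_input_transcripts
            - report.n_removed_no_gene_id
            - report.n_removed_all_zero
            - report.n_removed_redundant
        )

    def test_clean_unique_matrix_is_untouched(self, small_matrix):
        genes = gene_table({g: f"gene_{g}" for g in small_matrix.gene_ids})
        out, report = sg.preprocess_pipeline(small_matrix, genes)
        np.testing.assert_array_equal(out.values, small_matrix.values)
        assert report.n_removed_no_gene_id == 0
        assert report.n_removed_all_zero == 0
        assert report.n_removed_redundant == 0
        assert report.substitution_value is None

    def test_gene_lost_when_only_expressed_transcript_is_unannotated(self):
        # GeneA's expressed transcript lacks annotation; its annotated
        # transcript is all-zero, so the gene disappears entirely.
        matrix = make_matrix([[3.0, 4.0], [0.0, 0.0], [1.0, 1.0]],
                             gene_ids=["t1", "t2", "t3"])
        genes = gene_table({"t1": "", "t2": "GeneA", "t3": "GeneB"})
        out, report = sg.preprocess_pipeline(matrix, genes)
        assert out.gene_ids == ["GeneB"]
        assert report.n_removed_no_gene_id == 1
        assert report.n_removed_all_zero == 1

    def test_idempotent_on_its_own_output(self, small_study):
        _, matrix, _, genes, _ = small_study
        clean, _ = sg.preprocess_pipeline(matrix, genes)
        identity_genes = gene_table({g: g for g in clean.gene_ids})
        again, report = sg.preprocess_pipeline(clean, identity_genes)
        np.testing.assert_array_equal(again.values, clean.values)
        assert again.gene_ids == clean.gene_ids
        assert report.n_output_genes == report.n_input_transcripts

    def test_output_invariants(self, preprocessed_default):
        clean, report, _ = preprocessed_default
        assert len(set(clean.gene_ids)) == clean.n_genes
        assert (clean.values > 0).all()

    def test_sample_columns_never_modified(self, small_study):
        _, matrix, _, genes, _ = small_study
        clean, _ = sg.preprocess_pipeline(matrix, genes)
        assert clean.sample_ids == matrix.sample_ids
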