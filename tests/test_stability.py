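import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import segscan as sg
from conftest import make_matrix

positive_vectors = st.lists(
    st.floats(min_value=1e-6, max_value=1e6, allow_nan=False, allow_infinity=False),
    min_size=4,
    max_size=24,
)


class TestTrimmedFoldChange:
    @pytest.mark.parametrize(
        "values, trim_k, expected",
        [
            # sort-and-index oracle: sorted [1,2,3,4,100] -> 2nd high 4, 2nd low 2
            ([1, 2, 3, 4, 100], 1, (2.0, 4.0, 2.0)),
            # duplicates occupy distinct sorted positions
            ([2, 2, 8, 8], 1, (4.0, 8.0, 2.0)),
            ([5, 5, 5, 5], 1, (1.0, 5.0, 5.0)),
            ([5, 5, 5, 5], 0, (1.0, 5.0, 5.0)),
            ([10, 1, 5, 2, 8, 40], 2, (1.6, 8.0, 5.0)),
        ],
    )
    def test_against_sort_and_index_oracle(self, values, trim_k, expected):
        fc, upper, lower = sg.trimmed_fold_change(values, trim_k)
        assert (fc, upper, lower) == expected

    def test_asymmetric_trim(self):
        # drop the two highest but only the single lowest value
        result = sg.trimmed_fold_change([1, 2, 3, 4, 100], k_high=2, k_low=1)
        assert result == (1.5, 3.0, 2.0)

    def test_rejects_non_positive_values(self):
        with pytest.raises(ValueError, match="strictly positive"):
            sg.trimmed_fold_change([0.0, 1.0, 2.0, 3.0], 1)

    def test_rejects_vector_too_short_for_trim(self):
        with pytest.raises(ValueError, match="at least 6"):
            sg.trimmed_fold_change([1, 2, 3, 4], 2)

    @given(positive_vectors)
    def test_fc_at_least_one(self, values):
        fc, upper, lower = sg.trimmed_fold_change(values, 1)
        assert fc >= 1.0
        assert lower > 0
        assert upper >= lower

    @given(positive_vectors, st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, values, constant):
        base = sg.trimmed_fold_change(values, 1).fc
        scaled = sg.trimmed_fold_change([constant * v for v in values], 1).fc
        assert math.isclose(base, scaled, rel_tol=1e-9)

    @given(positive_vectors)
    def test_fc_non_increasing_in_trim(self, values):
        max_trim = len(values) // 2 - 1
        fcs = [sg.trimmed_fold_change(values, k).fc for k in range(max_trim + 1)]
        for lower_trim, higher_trim in zip(fcs, fcs[1:]):
            assert higher_trim <= lower_trim * (1 + 1e-12)

    @given(positive_vectors)
    def test_outlier_on_extreme_value_leaves_trimmed_fc_unchanged(self, values):
        """Inflating the current maximum (or deflating the minimum) by 1e6
        cannot move the trim-1 fold change: the aberrant value is exactly
        what the trim discards."""
        baseline = sg.trimmed_fold_change(values, 1).fc
        arr = np.asarray(values, dtype=float)
        spiked = arr.copy()
        spiked[arr.argmax()] *= 1e6
        assert sg.trimmed_fold_change(spiked, 1).fc == baseline
        cratered = arr.copy()
        cratered[arr.argmin()] /= 1e6
        assert sg.trimmed_fold_change(cratered, 1).fc == baseline

    @given(positive_vectors, st.data())
    def test_single_outlier_bounded_by_untrimmed_fc(self, values, data):
        """One aberrant cell anywhere can never push the trim-1 fold change
        beyond the gene's untrimmed max/min ratio."""
        untrimmed = sg.trimmed_fold_change(values, 0).fc
        position = data.draw(st.integers(0, len(values) - 1))
        up = data.draw(st.booleans())
        arr = np.asarray(values, dtype=float)
        arr[position] = arr[position] * 1e6 if up else arr[position] / 1e6
        assert sg.trimmed_fold_change(arr, 1).fc <= untrimmed * (1 + 1e-12)


class TestCallSegs:
    def test_boundary_fc_is_inclusive(self):
        # gene g1 has trim-1 fc exactly 4.0
        matrix = make_matrix([[1.0, 2.0, 8.0, 100.0], [1.0, 1.0, 50.0, 50.0]])
        calls = sg.call_segs(matrix, threshold=4.0, trim_k=1)
        assert calls.loc["g1", "fc"] == 4.0
        assert bool(calls.loc["g1", "is_seg"])
        assert not bool(calls.loc["g2", "is_seg"])

    def test_planted_genes_recovered_exactly(self, clean_study):
        design, matrix, _, genes, truth = clean_study
        clean, _ = sg.preprocess_pipeline(matrix, genes)
        threshold = (design.stable_fc_max + design.variable_fc_min) / 2
        segs = sg.seg_gene_set(clean, threshold, trim_k=1)
        assert segs == set(truth.stable_genes)

    def test_threshold_one_on_noisy_matrix_gives_no_segs(self):
        rng = np.random.default_rng(5)
        matrix = make_matrix(rng.uniform(1, 2, size=(30, 10)))
        assert sg.seg_gene_set(matrix, threshold=1.0, trim_k=1) == set()


class TestSegGrid:
    def test_default_grid_shape(self):
        matrix = make_matrix(np.random.default_rng(0).uniform(1, 9, (20, 12)))
        grid = sg.seg_grid(matrix)
        assert grid.counts.shape == (3, 5)
        assert grid.thresholds == (3.0, 4.0, 5.0)
        assert grid.trims == (0, 1, 2, 3, 4)

    def test_counts_match_per_gene_loop(self):
        rng = np.random.default_rng(11)
        values = 10 ** rng.normal(1, 1, size=(40, 14))
        matrix = make_matrix(values)
        grid = sg.seg_grid(matrix, thresholds=(2, 4, 8), trims=(0, 1, 2))
        for i, threshold in enumerate(grid.thresholds):
            for j, trim_k in enumerate(grid.trims):
                expected = sum(
                    sg.trimmed_fold_change(row, trim_k).fc <= threshold
                    for row in values
                )
                assert grid.counts[i, j] == expected

    def test_monotone_in_threshold_and_trim(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            matrix = make_matrix(10 ** rng.normal(0, 1.5, size=(30, 12)))
            grid = sg.seg_grid(matrix, thresholds=(2, 3, 4, 5), trims=(0, 1, 2, 3))
            assert (np.diff(grid.counts, axis=0) >= 0).all()
            assert (np.diff(grid.counts, axis=1) >= 0).all()

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            sg.SegGrid(thresholds=(3.0, 4.0), trims=(0,), counts=np.array([[5], [4]]))


class TestFcDistributionSummary:
    def test_median_of_three(self):
        matrix = make_matrix(
            [[1, 1, 1, 2], [1, 1, 1, 4], [1, 1, 1, 8]]
        )
        summary = sg.fc_distribution_summary(matrix, trim_k=0)
        assert summary["fc_median"] == 4.0
        assert summary["fc_min"] == 2.0
        assert summary["fc_max"] == 8.0

    def test_single_gene_degenerate(self):
        matrix = make_matrix([[1, 2, 3, 6]])
        summary = sg.fc_distribution_summary(matrix, trim_k=0)
        assert summary["fc_min"] == summary["fc_max"] == summary["fc_median"] == 6.0

    def test_median_matches_sort_oracle_and_histogram_totals(self):
        rng = np.random.default_rng(9)
        values = 10 ** rng.normal(0, 2, size=(1000, 10))
        matrix = make_matrix(values)
        summary = sg.fc_distribution_summary(matrix, trim_k=1)
        fcs = sorted(sg.trimmed_fold_change(row, 1).fc for row in values)
        mid = (fcs[499] + fcs[500]) / 2  # midpoint convention at even count
        assert math.isclose(summary["fc_median"], mid, rel_tol=1e-12)
        assert sum(summary["bin_counts"]) == 1000
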