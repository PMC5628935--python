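import numpy as np
import pandas as pd
import pytest

from splsero import NPXMatrix
from splsero.preprocess import (
    ReferenceDistribution,
    detect_excludable_proteins,
    exact_independence_test,
    normalize_against_reference,
    project_matrix,
    quantile_normalize,
    reset_below_lod,
)


def _matrix_with_mask(mask: np.ndarray) -> NPXMatrix:
    """Values are irrelevant for exclusion; mask drives everything."""
    n, p = mask.shape
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"S{i}" for i in range(n)],
        columns=[f"P{j}" for j in range(p)],
    )
    below = pd.DataFrame(mask, index=values.index, columns=values.columns)
    return NPXMatrix(values, below)


class TestExactIndependenceTest:
    # reference p-values from R stats::fisher.test on the same tables
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[1, 1, 1], [9, 9, 9]], 1.0),
            ([[1, 10, 10], [9, 0, 0]], 2.096853671e-06),
            ([[2, 5, 7], [8, 5, 3]], 0.106120005),
            ([[3, 7], [9, 1]], 0.0197666111),
        ],
    )
    def test_matches_r_fisher(self, table, expected):
        assert exact_independence_test(np.array(table)) == pytest.approx(expected, rel=1e-8)

    def test_degenerate_margins_give_one(self):
        assert exact_independence_test(np.array([[0, 0, 0], [5, 5, 5]])) == 1.0


class TestDetectExcludable:
    def test_fully_detected_matrix_flags_nothing(self, three_group_annot):
        annot = three_group_annot(4)
        matrix = _matrix_with_mask(np.zeros((12, 3), dtype=bool))
        matrix.values.index = annot.index
        matrix.below_lod.index = annot.index
        out = detect_excludable_proteins(matrix, annot)
        assert not out["excluded"].any()

    def test_even_censoring_flagged_uneven_not(self, three_group_annot):
        annot = three_group_annot(10)
        # protein 0: censored 9/9/9 across groups (even); protein 1:
        # censoring concentrated in CD (25 = 10 CD + 10 UC + 5 HC is even-ish,
        # use 10/10/5 detected 0/0/5 -> uneven)
        mask = np.zeros((30, 2), dtype=bool)
        groups = annot["group"].to_numpy()
        for g in ("CD", "UC", "HC"):
            idx = np.flatnonzero(groups == g)[:9]
            mask[idx, 0] = True
        mask[np.flatnonzero(groups == "CD"), 1] = True
        mask[np.flatnonzero(groups == "UC"), 1] = True
        mask[np.flatnonzero(groups == "HC")[:5], 1] = True
        matrix = _matrix_with_mask(mask)
        matrix.values.index = annot.index
        matrix.below_lod.index = annot.index
        out = detect_excludable_proteins(matrix, annot)
        assert bool(out.loc["P0", "excluded"])
        assert bool(out.loc["P1", "prevalence_exceeded"])
        assert not bool(out.loc["P1", "evenly_distributed"])
        assert not bool(out.loc["P1", "excluded"])

    def test_default_study_drops_designated_assays(self, processed_discovery):
        exclusion = processed_discovery["exclusion"]
        dropped = set(exclusion.index[exclusion["excluded"]])
        assert dropped == {"IL-13", "IL-33", "IL-1 alpha", "TSLP"}

    def test_invariant_to_value_transform_and_sample_order(self, three_group_annot):
        annot = three_group_annot(10)
        rng = np.random.default_rng(5)
        mask = rng.random((30, 4)) < 0.85
        matrix = _matrix_with_mask(mask)
        matrix.values.index = annot.index
        matrix.below_lod.index = annot.index
        base = detect_excludable_proteins(matrix, annot)

        transformed = NPXMatrix(np.exp(matrix.values), matrix.below_lod.copy())
        out = detect_excludable_proteins(transformed, annot)
        pd.testing.assert_frame_equal(base, out)

        perm = rng.permutation(len(annot))
        shuffled = NPXMatrix(matrix.values.iloc[perm], matrix.below_lod.iloc[perm])
        out = detect_excludable_proteins(shuffled, annot)
        pd.testing.assert_frame_equal(base, out)


class TestQuantileNormalize:
    def test_three_by_four_matches_brute_force(self):
        values = pd.DataFrame(
            [[5.0, 2.0, 3.0, 9.0], [4.0, 1.0, 4.5, 7.0], [6.0, 8.0, 3.0, 5.0]],
            index=["a", "b", "c"],
            columns=list("wxyz"),
        )
        out, ref = quantile_normalize(NPXMatrix(values))
        # independent brute force: mean of sorted rows, reassigned by rank
        expected_ref = np.vstack([np.sort(r) for r in values.to_numpy()]).mean(axis=0)
        np.testing.assert_allclose(ref.quantiles, expected_ref)
        for i, row in enumerate(values.to_numpy()):
            order = np.argsort(row)
            expected = np.empty(4)
            expected[order] = expected_ref  # no ties in this fixture
            np.testing.assert_allclose(out.values.iloc[i].to_numpy(), expected)

    def test_permutation_symmetric_samples(self):
        values = pd.DataFrame(
            [[1.0, 4.0, 2.0], [2.0, 1.0, 4.0]], index=["a", "b"], columns=list("xyz")
        )
        out, ref = quantile_normalize(NPXMatrix(values))
        np.testing.assert_allclose(np.sort(out.values.iloc[0]), np.sort(values.iloc[0]))
        np.testing.assert_allclose(np.sort(out.values.iloc[1]), np.sort(values.iloc[1]))

    def test_identical_samples_fixed_point(self):
        values = pd.DataFrame(
            [[1.0, 3.0, 2.0]] * 3, index=list("abc"), columns=list("xyz")
        )
        out, _ = quantile_normalize(NPXMatrix(values))
        pd.testing.assert_frame_equal(out.values, values)

    def test_all_sorted_vectors_identical_afterwards(self):
        rng = np.random.default_rng(11)
        values = pd.DataFrame(
            rng.normal(size=(10, 25)),
            index=[f"s{i}" for i in range(10)],
            columns=[f"p{j}" for j in range(25)],
        )
        out, ref = quantile_normalize(NPXMatrix(values))
        sorted_rows = np.sort(out.values.to_numpy(), axis=1)
        np.testing.assert_allclose(sorted_rows, np.tile(ref.quantiles, (10, 1)))

    def test_single_sample_directed_to_reference_projection(self):
        values = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=list("xy"))
        with pytest.raises(ValueError, match="normalize_against_reference"):
            quantile_normalize(NPXMatrix(values))

    def test_tie_handling_averages_spanned_reference(self):
        values = pd.DataFrame(
            [[1.0, 1.0, 5.0], [2.0, 3.0, 4.0]], index=["a", "b"], columns=list("xyz")
        )
        out, ref = quantile_normalize(NPXMatrix(values))
        tied = out.values.loc["a", ["x", "y"]].to_numpy()
        assert tied[0] == tied[1] == pytest.approx(ref.quantiles[:2].mean())


class TestReferenceProjection:
    def test_projection_sorted_equals_reference(self):
        ref = ReferenceDistribution(np.array([0.0, 1.0, 2.5, 4.0]), 10)
        out = normalize_against_reference(np.array([9.0, -3.0, 0.5, 2.0]), ref)
        np.testing.assert_allclose(np.sort(out), ref.quantiles)

    def test_idempotent(self):
        ref = ReferenceDistribution(np.array([0.0, 1.0, 2.5, 4.0]), 10)
        once = normalize_against_reference(np.array([9.0, -3.0, 0.5, 2.0]), ref)
        twice = normalize_against_reference(once, ref)
        np.testing.assert_allclose(once, twice)

    def test_reference_input_unchanged(self):
        ref = ReferenceDistribution(np.array([0.0, 1.0, 2.5]), 5)
        out = normalize_against_reference(np.array([2.5, 0.0, 1.0]), ref)
        np.testing.assert_allclose(out, [2.5, 0.0, 1.0])

    def test_length_mismatch_raises(self):
        ref = ReferenceDistribution(np.array([0.0, 1.0]), 5)
        with pytest.raises(ValueError, match="length"):
            normalize_against_reference(np.array([1.0, 2.0, 3.0]), ref)

    def test_self_projection_of_normalized_cohort_is_identity(self, processed_discovery):
        matrix = processed_discovery["matrix"]
        ref = processed_discovery["reference"]
        # the processed matrix has below-LOD resets; project the pre-reset
        # normalized values instead: every sample already carries the
        # reference multiset, so projection must be the identity
        normalized = NPXMatrix(matrix.values.copy(), matrix.below_lod.copy())
        normalized.values[matrix.below_lod] = np.nan  # mark resets
        sample = matrix.values.iloc[0].to_numpy()
        if not matrix.below_lod.iloc[0].any():
            out = normalize_against_reference(sample, ref)
            np.testing.assert_allclose(np.sort(out), np.sort(sample))


class TestResetBelowLOD:
    def test_all_false_mask_is_identity(self, small_matrix):
        mask = small_matrix.below_lod.copy()
        mask.loc[:, :] = False
        matrix = NPXMatrix(small_matrix.values.copy(), mask)
        out = reset_below_lod(matrix)
        pd.testing.assert_frame_equal(out.values, matrix.values)

    def test_only_masked_cells_zeroed(self, small_matrix):
        out = reset_below_lod(small_matrix)
        assert out.values.loc["S1", "P1"] == 0.0
        assert out.values.loc["S2", "P3"] == 0.0
        assert out.values.loc["S3", "P2"] == small_matrix.values.loc["S3", "P2"]
        assert int((out.values.to_numpy() == 0).sum()) == 2

    def test_censoring_rate_matches_generator(self, default_study):
        matrix, _, _, _ = default_study["discovery"]
        ordinary = [p for p in matrix.protein_ids
                    if p not in {"IL-13", "IL-33", "IL-1 alpha", "TSLP"}]
        frac = matrix.below_lod[ordinary].to_numpy().mean()
        assert frac == pytest.approx(0.02, abs=0.005)

    def test_reset_order_changes_results(self, small_matrix):
        values = pd.DataFrame(
            np.random.default_rng(2).normal(size=(4, 5)),
            index=list("abcd"),
            columns=list("vwxyz"),
        )
        mask = values < values.quantile(0.25)
        matrix = NPXMatrix(values, mask)
        # required order: normalize then reset
        normalized, _ = quantile_normalize(matrix)
        after = reset_below_lod(normalized).values
        # wrong order: reset then normalize
        pre_reset = reset_below_lod(matrix)
        wrong, _ = quantile_normalize(pre_reset)
        assert not np.allclose(after.to_numpy(), wrong.values.to_numpy())
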