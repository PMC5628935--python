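import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splsero import fit_splsda, pca_scores, predict, soft_threshold, vip_scores


def _standardize_blocks(X, labels):
    """Independent reference standardization mirroring the model contract."""
    classes = np.unique(labels)
    Y = (np.asarray(labels)[:, None] == classes[None, :]).astype(float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    Ys = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)
    return Xs, Ys


def _dense_pls_oracle(X, labels, n_components):
    """SVD-based dense PLS-DA weights with regression-mode deflation."""
    Xs, Ys = _standardize_blocks(X, labels)
    Xh, Yh = Xs.copy(), Ys.copy()
    W = []
    for _ in range(n_components):
        U, s, Vt = np.linalg.svd(Xh.T @ Yh, full_matrices=False)
        u = U[:, 0]
        if u[np.argmax(np.abs(u))] < 0:
            u = -u
        t = Xh @ u
        tt = t @ t
        Xh = Xh - np.outer(t, Xh.T @ t / tt)
        Yh = Yh - np.outer(t, Yh.T @ t / tt)
        W.append(u)
    return np.column_stack(W)


class TestSoftThreshold:
    def test_keep_all_is_rescaled_identity(self):
        w = np.array([3.0, -1.0, 0.5])
        out = soft_threshold(w, 3)
        np.testing.assert_allclose(out, w / np.linalg.norm(w))

    def test_keep_two_shrinks_by_third_largest(self):
        out = soft_threshold(np.array([3.0, -1.0, 0.5]), 2)
        expected = np.array([2.5, -0.5, 0.0])
        np.testing.assert_allclose(out, expected / np.linalg.norm(expected))

    def test_complete_tie_keeps_first_index(self):
        out = soft_threshold(np.array([1.0, -1.0, 1.0]), 1)
        np.testing.assert_allclose(out, [1.0, 0.0, 0.0])

    def test_invalid_keep_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(3), 0)
        with pytest.raises(ValueError):
            soft_threshold(np.ones(3), 4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=20),
        st.data(),
    )
    def test_unit_norm_and_sparsity(self, values, data):
        w = np.array(values)
        keep = data.draw(st.integers(1, len(values)))
        out = soft_threshold(w, keep)
        assert np.count_nonzero(out) <= keep
        norm = np.linalg.norm(out)
        assert norm == pytest.approx(1.0) or (norm == 0.0 and not w.any())


@pytest.fixture
def toy_classes():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(24, 8))
    X[:12, :3] += 1.5
    labels = np.array(["A"] * 12 + ["B"] * 12)
    return X, labels


class TestFitSPLSDA:
    def test_dense_limit_matches_svd_oracle(self, toy_classes):
        X, labels = toy_classes
        model = fit_splsda(X, labels, n_components=2, keepX=None)
        W_oracle = _dense_pls_oracle(X, labels, 2)
        for h in range(2):
            cos = abs(model.W[:, h] @ W_oracle[:, h])
            assert cos > 1 - 1e-8

    def test_separable_clouds_zero_training_error(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 10))
        X[:15] += 4.0
        labels = np.array(["pos"] * 15 + ["neg"] * 15)
        model = fit_splsda(X, labels, n_components=1, keepX=5)
        _, pred = predict(model, X)
        assert (pred == labels).all()

    def test_score_orthogonality(self, toy_classes):
        X, labels = toy_classes
        model = fit_splsda(X, labels, n_components=3, keepX=4)
        G = model.T.T @ model.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_sample_order_invariance(self, toy_classes):
        X, labels = toy_classes
        model = fit_splsda(X, labels, n_components=2)
        perm = np.random.default_rng(9).permutation(len(labels))
        model_p = fit_splsda(X[perm], labels[perm], n_components=2)
        for h in range(2):
            cos = abs(model.W[:, h] @ model_p.W[:, h])
            assert cos == pytest.approx(1.0, abs=1e-10)

    def test_keepx_bounds_nonzeros(self, toy_classes):
        X, labels = toy_classes
        model = fit_splsda(X, labels, n_components=2, keepX=[3, 2])
        assert np.count_nonzero(model.W[:, 0]) <= 3
        assert np.count_nonzero(model.W[:, 1]) <= 2
        np.testing.assert_allclose(np.linalg.norm(model.W, axis=0), 1.0)

    def test_constant_column_dropped_with_warning(self, toy_classes):
        X, labels = toy_classes
        X = np.column_stack([X, np.ones(len(labels))])
        with pytest.warns(UserWarning, match="constant"):
            model = fit_splsda(X, labels, n_components=1)
        assert len(model.features) == X.shape[1] - 1


class TestPredict:
    def test_matches_iterative_projection_oracle(self, toy_classes):
        X, labels = toy_classes
        model = fit_splsda(X, labels, n_components=2, keepX=4)
        rng = np.random.default_rng(8)
        X_new = rng.normal(size=(5, X.shape[1]))
        scores, _ = predict(model, X_new)
        # independent route: project component by component with deflation
        Xs = (X_new - model.x_mean) / model.x_scale
        yhat = np.zeros((5, len(model.classes_)))
        Xh = Xs.copy()
        for h in range(model.n_components):
            t = Xh @ model.W[:, h]
            Xh = Xh - np.outer(t, model.P[:, h])
            yhat += np.outer(t, model.Q[:, h])
        expected = yhat * model.y_scale + model.y_mean
        np.testing.assert_allclose(scores, expected, atol=1e-10)

    def test_zero_components_predicts_majority_class(self):
        X = np.random.default_rng(0).normal(size=(9, 4))
        labels = np.array(["maj"] * 6 + ["min"] * 3)
        model = fit_splsda(X, labels, n_components=0)
        _, pred = predict(model, X)
        assert (pred == "maj").all()

    def test_missing_protein_column_raises(self, toy_classes):
        import pandas as pd

        X, labels = toy_classes
        Xdf = pd.DataFrame(X, columns=[f"prot{i}" for i in range(X.shape[1])])
        model = fit_splsda(Xdf, labels, n_components=1)
        with pytest.raises(ValueError, match="missing"):
            predict(model, Xdf.drop(columns=["prot0"]))


class TestVIP:
    def test_single_component_closed_form(self, toy_classes):
        X, labels = toy_classes
        model = fit_splsda(X, labels, n_components=1, keepX=None)
        vip = vip_scores(model)
        p = X.shape[1]
        np.testing.assert_allclose(vip, np.sqrt(p) * np.abs(model.W[:, 0]))
        assert (vip**2).mean() == pytest.approx(1.0)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(6, 4))
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        model = fit_splsda(X, labels, n_components=2)
        vip = vip_scores(model)
        p = 4
        expected = np.zeros(p)
        for j in range(p):
            num = sum(model.ssy[h] * model.W[j, h] ** 2 for h in range(2))
            expected[j] = np.sqrt(p * num / model.ssy.sum())
        np.testing.assert_allclose(vip, expected)
        assert (vip**2).mean() == pytest.approx(1.0)

    def test_thresholded_out_proteins_score_zero(self, toy_classes):
        X, labels = toy_classes
        model = fit_splsda(X, labels, n_components=2, keepX=2)
        vip = vip_scores(model)
        never_used = ~np.any(model.W != 0, axis=1)
        assert never_used.any()
        np.testing.assert_allclose(vip[never_used], 0.0)

    def test_top10_recovery_on_informative_proteins(self):
        hits = []
        for seed in range(20):
            rng = np.random.default_rng([seed, 77])
            X = rng.normal(0, 0.5, (108, 87))
            X[:54, :10] += np.where(np.arange(10) % 2, 1.0, -1.0)
            labels = np.array(["CD"] * 54 + ["HC"] * 54)
            vip = vip_scores(fit_splsda(X, labels, n_components=2))
            hits.append(len(set(np.argsort(-vip)[:10]) & set(range(10))))
        assert np.mean(hits) >= 8.0


class TestPCAScores:
    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(12, 5))
        scores = pca_scores(X, k=3)
        Xc = X - X.mean(axis=0)
        Xc /= Xc.std(axis=0, ddof=1)
        U, S, _ = np.linalg.svd(Xc, full_matrices=False)
        np.testing.assert_allclose(np.abs(scores), np.abs(U[:, :3] * S[:3]), atol=1e-10)

    def test_dominant_direction_on_pc1(self):
        rng = np.random.default_rng(4)
        coeff = rng.normal(size=20)
        X = np.outer(coeff, rng.normal(size=6)) + rng.normal(scale=1e-3, size=(20, 6))
        s1 = pca_scores(X, k=1, scale=False)[:, 0]
        r = np.corrcoef(s1, coeff - coeff.mean())[0, 1]
        assert abs(r) > 0.999

    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 4))
        X = np.vstack([X, X[0]])
        scores = pca_scores(X, k=2)
        np.testing.assert_allclose(scores[0], scores[-1], atol=1e-10)

    def test_rank_truncation_warns(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 2))
        X = np.column_stack([X, X[:, 0]])  # duplicated column: rank 2
        with pytest.warns(UserWarning, match="rank"):
            scores = pca_scores(X, k=3, scale=False)
        assert scores.shape == (5, 2)
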