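import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnomet import (
    DataError,
    hotelling_outliers,
    label_permutation_test,
    pca_fit,
    plsda_fit,
    q2_cross_validate,
    select_top_vip,
    vip_scores,
)
from somnomet.multivariate import _nipals_pls2, _one_hot, _separation_statistic, plsda_predict


def two_group_data(rng, n_per=10, p=50, n_effect=10, effect_sd=3.0):
    """Gaussian matrix with the first n_effect columns shifted in group A."""
    X = rng.normal(size=(2 * n_per, p))
    X[:n_per, :n_effect] += effect_sd
    labels = ["A"] * n_per + ["B"] * n_per
    return X, labels


class TestPca:
    def test_collinear_data_loads_on_single_component(self):
        t = np.linspace(-1, 1, 7)
        X = np.column_stack([t, 2 * t])
        m = pca_fit(X, 1)
        assert m.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_scores_covariance_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(8, 5))
        m = pca_fit(X, 4)
        Xc = X - X.mean(axis=0)
        eigvals = np.linalg.eigvalsh(np.cov(Xc, rowvar=False))[::-1]
        cov_scores = np.diag(np.cov(m.scores, rowvar=False))
        assert np.allclose(cov_scores, eigvals[:4], atol=1e-10)
        assert np.allclose(m.eigenvalues, eigvals[:4], atol=1e-10)

    def test_loadings_invariant_to_row_duplication(self, rng):
        X = rng.normal(size=(6, 4))
        m1 = pca_fit(X, 2)
        m2 = pca_fit(np.vstack([X, X]), 2)
        assert np.allclose(np.abs(m1.loadings), np.abs(m2.loadings), atol=1e-8)

    def test_sign_convention_largest_loading_positive(self, rng):
        m = pca_fit(rng.normal(size=(10, 6)), 3)
        for a in range(3):
            j = np.argmax(np.abs(m.loadings[:, a]))
            assert m.loadings[j, a] > 0

    def test_loadings_orthonormal(self, rng):
        m = pca_fit(rng.normal(size=(12, 7)), 4)
        assert np.allclose(m.loadings.T @ m.loadings, np.eye(4), atol=1e-8)

    def test_k_too_large_errors(self, rng):
        with pytest.raises(DataError, match="out of range"):
            pca_fit(rng.normal(size=(5, 3)), 5)


class TestHotelling:
    def test_single_extreme_sample_flagged_exactly(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(31, 5))
        X[7] = 0.0
        X[7, 0] = 50.0
        out = hotelling_outliers(pca_fit(X, 2))
        assert out == {7}

    def test_jittered_identical_points_give_empty_set(self, rng):
        X = np.ones((10, 4)) + 1e-9 * rng.normal(size=(10, 4))
        assert hotelling_outliers(pca_fit(X, 2)) == set()

    def test_three_planted_extremes_recovered_without_false_positives(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(30, 8))
        dirs = rng.normal(size=(3, 8))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        X[:3] += 50.0 * dirs
        assert hotelling_outliers(pca_fit(X, 2)) == {0, 1, 2}

    def test_null_flag_rate_near_nominal(self):
        # long-run per-sample flag rate on pure-null Gaussian data
        rng = np.random.default_rng(7)
        flags = total = 0
        for _ in range(200):
            X = rng.normal(size=(100, 20))
            flags += len(hotelling_outliers(pca_fit(X, 2)))
            total += 100
        assert 0.02 <= flags / total <= 0.09

    def test_tiny_n_errors(self, rng):
        with pytest.raises(DataError, match="n <= 3"):
            hotelling_outliers(pca_fit(rng.normal(size=(3, 4)), 2))


class TestPlsda:
    def test_dominant_metabolite_gets_largest_weight(self):
        n = 6
        X = np.zeros((2 * n, 4))
        X[:n, 2] = 5.0
        X[n:, 2] = -5.0
        m = plsda_fit(X + 1e-9, ["A"] * n + ["B"] * n, n_components=1)
        assert np.argmax(np.abs(m.x_weights[:, 0])) == 2

    def test_r2y_drops_under_label_permutation(self, rng):
        X, labels = two_group_data(rng)
        m_true = plsda_fit(X, labels, n_components=2)
        perm = list(rng.permutation(labels))
        m_perm = plsda_fit(X, perm, n_components=2)
        assert m_perm.r2y < m_true.r2y

    def test_nipals_matches_independent_eigen_transcription(self, rng):
        # component-1 weight solves the dominant eigenvector of X' Y Y' X;
        # deflation then repeats the same problem on the residual.
        X = rng.normal(size=(6, 4))
        labels = ["A", "A", "A", "B", "B", "B"]
        Y = _one_hot(np.asarray(labels), ["A", "B"])
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        m = plsda_fit(X, labels, n_components=2)
        Xr = Xc.copy()
        for a in range(2):
            M = Xr.T @ Yc @ Yc.T @ Xr
            vals, vecs = np.linalg.eigh(M)
            w = vecs[:, -1]
            if w[np.argmax(np.abs(w))] < 0:
                w = -w
            t = Xr @ w
            assert np.allclose(np.abs(w), np.abs(m.x_weights[:, a]), atol=1e-6)
            assert np.allclose(np.abs(t), np.abs(m.x_scores[:, a]), atol=1e-6)
            p_load = Xr.T @ t / (t @ t)
            Xr = Xr - np.outer(t, p_load)
            c = Yc.T @ t / (t @ t)
            Yc = Yc - np.outer(t, c)

    def test_component_one_agrees_with_sklearn_cross_check(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X, labels = two_group_data(rng, n_per=8, p=20, n_effect=5, effect_sd=1.5)
        m = plsda_fit(X, labels, n_components=2)
        Y = _one_hot(np.asarray(labels), ["A", "B"])
        sk = PLSRegression(n_components=2, scale=False).fit(X, Y - Y.mean(axis=0))
        r = np.corrcoef(m.x_scores[:, 0], sk.x_scores_[:, 0])[0, 1]
        assert abs(r) > 0.999

    def test_rotation_invariance_of_scores_and_r2y(self, rng):
        X, labels = two_group_data(rng, n_per=6, p=12, n_effect=4, effect_sd=2.0)
        R, _ = np.linalg.qr(rng.normal(size=(12, 12)))
        m1 = plsda_fit(X, labels, n_components=2)
        m2 = plsda_fit(X @ R, labels, n_components=2)
        assert np.allclose(np.abs(m1.x_scores), np.abs(m2.x_scores), atol=1e-6)
        assert m1.r2y == pytest.approx(m2.r2y, abs=1e-6)

    def test_single_class_errors(self, rng):
        with pytest.raises(DataError, match=">= 2 classes"):
            plsda_fit(rng.normal(size=(6, 3)), ["A"] * 6)


class TestVip:
    def test_single_metabolite_vip_is_one(self):
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.normal(0, 1, 4), rng.normal(3, 1, 4)])[:, None]
        m = plsda_fit(X, ["A"] * 4 + ["B"] * 4, n_components=1)
        assert m.vip[0] == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_mean_squared_vip_is_one(self, seed):
        rng = np.random.default_rng(seed)
        n_per = int(rng.integers(3, 8))
        p = int(rng.integers(2, 15))
        X = rng.normal(size=(2 * n_per, p))
        X[:n_per, 0] += rng.uniform(0.5, 3.0)
        A = int(rng.integers(1, min(2 * n_per - 1, p) + 1))
        m = plsda_fit(X, ["A"] * n_per + ["B"] * n_per, n_components=A)
        assert np.mean(m.vip**2) == pytest.approx(1.0, abs=1e-6)

    def test_vip_matches_formula_with_independent_ssy(self, rng):
        # SSY_a recomputed from incremental R2Y of nested refits
        X, labels = two_group_data(rng, n_per=4, p=4, n_effect=2, effect_sd=2.0)
        m = plsda_fit(X, labels, n_components=2)
        Y = _one_hot(np.asarray(labels), ["A", "B"])
        tss = np.sum((Y - Y.mean(axis=0)) ** 2)
        r2_prev = 0.0
        ssy = []
        for a in (1, 2):
            r2 = plsda_fit(X, labels, n_components=a).r2y
            ssy.append((r2 - r2_prev) * tss)
            r2_prev = r2
        ssy = np.array(ssy)
        p = X.shape[1]
        W = m.x_weights / np.linalg.norm(m.x_weights, axis=0)
        expected = np.sqrt(p * ((W**2) @ ssy) / ssy.sum())
        assert np.allclose(m.vip, expected, atol=1e-8)
        assert np.allclose(m.ssy, ssy, atol=1e-8)

    def test_zero_ssy_errors(self, rng):
        m = plsda_fit(*two_group_data(rng, n_per=4, p=5), n_components=1)
        m.ssy = np.zeros_like(m.ssy)
        with pytest.raises(DataError, match="VIP undefined"):
            vip_scores(m)


class TestSelectTopVip:
    def _model_with_vip(self, vip, ids):
        rng = np.random.default_rng(0)
        m = plsda_fit(rng.normal(size=(8, len(ids))) +
                      np.r_[np.zeros((4, len(ids))), np.ones((4, len(ids)))],
                      ["A"] * 4 + ["B"] * 4, n_components=1)
        m.vip = np.asarray(vip, dtype=float)
        m.metabolite_ids = list(ids)
        return m

    def test_fraction_ceiling(self):
        m = self._model_with_vip(np.arange(200), [f"m{j:03d}" for j in range(200)])
        assert len(select_top_vip(m, 0.05)) == 10

    def test_fraction_one_returns_all_sorted(self):
        m = self._model_with_vip([1.0, 3.0, 2.0], ["a", "b", "c"])
        assert select_top_vip(m, 1.0) == ["b", "c", "a"]

    def test_ties_broken_lexicographically(self):
        m = self._model_with_vip([2.0, 2.0, 2.0, 1.0], ["delta", "alpha", "charlie", "bravo"])
        assert select_top_vip(m, 0.25) == ["alpha"]


class TestQ2:
    def test_high_signal_q2_close_to_one(self, rng):
        X, labels = two_group_data(rng, n_per=10, p=20, n_effect=20, effect_sd=20.0)
        q2 = q2_cross_validate(X, labels, n_components=2, folds=10, seed=0)
        assert q2 >= 0.9

    def test_null_q2_is_low_in_most_replicates(self):
        rng = np.random.default_rng(1)
        low = 0
        for i in range(50):
            X = rng.normal(size=(20, 50))
            q2 = q2_cross_validate(X, ["A"] * 10 + ["B"] * 10,
                                   n_components=3, folds=10, seed=i)
            low += q2 <= 0.2
        assert low >= 45

    def test_loo_equals_explicit_loop_oracle(self, rng):
        X, labels = two_group_data(rng, n_per=4, p=6, n_effect=3, effect_sd=2.0)
        n = len(labels)
        press = tss = 0.0
        for i in range(n):
            train = [j for j in range(n) if j != i]
            m = plsda_fit(X[train], [labels[j] for j in train], n_components=2)
            y_mean = m.y_mean
            yte = _one_hot(np.asarray([labels[i]]), m.class_levels)
            yhat = plsda_predict(m, X[[i]])
            press += float(np.sum((yte - yhat) ** 2))
            tss += float(np.sum((yte - y_mean) ** 2))
        oracle = 1.0 - press / tss
        assert q2_cross_validate(X, labels, n_components=2, folds=n) == pytest.approx(oracle, abs=1e-10)

    def test_fold_lacking_class_errors_before_fitting(self, rng):
        X, labels = two_group_data(rng, n_per=4, p=5)
        with pytest.raises(DataError, match="lack"):
            q2_cross_validate(X, labels, folds=6, seed=0)


class TestLabelPermutation:
    def test_constant_data_gives_large_p(self):
        X = np.ones((12, 5))
        p = label_permutation_test(X, ["A"] * 6 + ["B"] * 6, n_perm=99, seed=0)
        assert p >= 0.5

    def test_planted_effect_detected(self, rng):
        X, labels = two_group_data(rng, n_per=10, p=50, n_effect=20, effect_sd=1.5)
        p = label_permutation_test(X, labels, n_perm=199, seed=1)
        assert p <= 0.05

    def test_monte_carlo_close_to_exhaustive_enumeration(self, rng):
        X = rng.normal(size=(6, 4))
        X[:3, 0] += 1.0
        labels = np.array(["A"] * 3 + ["B"] * 3)
        Y = _one_hot(labels, ["A", "B"])
        Xc = X - X.mean(axis=0)

        def stat(lab):
            Yl = _one_hot(lab, ["A", "B"])
            _, T, _, _, _ = _nipals_pls2(Xc, Yl - Yl.mean(axis=0), 1)
            return _separation_statistic(T[:, 0], lab)

        obs = stat(labels)
        stats_all = []
        for combo in itertools.combinations(range(6), 3):
            lab = np.array(["B"] * 6)
            for i in combo:
                lab[i] = "A"
            stats_all.append(stat(lab))
        exhaustive = np.mean([s >= obs - 1e-12 for s in stats_all])
        p_mc = label_permutation_test(X, labels, n_perm=2000, seed=3)
        assert abs(p_mc - exhaustive) <= 0.02

    def test_vip_recovery_of_planted_metabolites(self):
        # >= 80% of 30 planted 1.8x metabolites inside the top-15% VIP list
        from somnomet import MetabolomeSimSpec, preprocess, simulate_metabolome

        hits = []
        for rep in range(5):
            planted = {(f"M{j + 1:04d}", "REM"): 1.8 for j in range(30)}
            spec = MetabolomeSimSpec(n_metabolites=200,
                                     group_sizes={"REM": 10, "Wake": 10},
                                     planted_effects=planted, cv_noise=0.2,
                                     seed=100 + rep)
            table, _ = simulate_metabolome(spec)
            proc = preprocess(table)
            m = plsda_fit(proc, table.annotations["state"].tolist(), n_components=3)
            top = set(select_top_vip(m, 0.15))
            hits.append(len(top & {f"M{j + 1:04d}" for j in range(30)}) / 30)
        assert np.median(hits) >= 0.8
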