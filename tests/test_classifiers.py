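import dataclasses

import numpy as np
import pytest

from hiset import classifiers as clf


def blobs(seed=0, n=100, d=4, sep=6.0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.standard_normal((n, d)), rng.standard_normal((n, d)) + sep])
    y = np.array([0] * n + [1] * n)
    perm = rng.permutation(2 * n)
    return X[perm], y[perm]


class TestELM:
    def test_exact_interpolation(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 5))
        y = rng.integers(0, 2, 20)
        model = clf.elm_train(X, y, hidden_count=20, seed=1)
        _, scores = clf.elm_predict(model, X, return_scores=True)
        T = (y[:, None] == model.classes[None, :]).astype(float)
        assert np.mean((scores - T) ** 2) < 1e-6

    def test_blob_accuracy(self):
        X, y = blobs(seed=1)
        tr, te = np.arange(150), np.arange(150, 200)
        model = clf.elm_train(X[tr], y[tr], hidden_count=30, seed=2)
        assert np.mean(clf.elm_predict(model, X[tr]) == y[tr]) >= 0.99
        assert np.mean(clf.elm_predict(model, X[te]) == y[te]) >= 0.95

    def test_determinism(self):
        X, y = blobs(seed=2, n=30)
        a = clf.elm_train(X, y, hidden_count=10, seed=3)
        b = clf.elm_train(X, y, hidden_count=10, seed=3)
        assert np.array_equal(a.output_weights, b.output_weights)

    def test_score_linearity(self):
        X, y = blobs(seed=3, n=20)
        model = clf.elm_train(X, y, hidden_count=8, seed=0)
        _, s1 = clf.elm_predict(model, X, return_scores=True)
        model.output_weights = 2 * model.output_weights
        _, s2 = clf.elm_predict(model, X, return_scores=True)
        assert np.allclose(s2, 2 * s1)

    def test_training_error_non_increasing_in_hidden_count(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 6))
        y = rng.integers(0, 3, 60)
        T = (y[:, None] == np.unique(y)[None, :]).astype(float)
        w_full = rng.uniform(-1, 1, (40, 6))
        b_full = rng.uniform(-1, 1, 40)
        errors = []
        for L in (5, 10, 20, 40):
            H = clf._elm_hidden(w_full[:L], b_full[:L], X)
            beta = np.linalg.pinv(H) @ T
            errors.append(np.mean((H @ beta - T) ** 2))
        assert all(a >= b - 1e-12 for a, b in zip(errors, errors[1:]))

    def test_dimension_mismatch(self):
        X, y = blobs(seed=5, n=10)
        model = clf.elm_train(X, y, hidden_count=5, seed=0)
        with pytest.raises(ValueError):
            clf.elm_predict(model, np.zeros((3, 7)))

    def test_invalid_hidden_count(self):
        with pytest.raises(ValueError):
            clf.elm_train(np.zeros((4, 2)), np.zeros(4), hidden_count=0)


def planted_dictionary(seed, d=16, m=20, n=1200, l0=3):
    rng = np.random.default_rng(seed)
    D0 = rng.standard_normal((d, m))
    D0 /= np.linalg.norm(D0, axis=0)
    C0 = np.zeros((m, n))
    for j in range(n):
        idx = rng.choice(m, l0, replace=False)
        C0[idx, j] = rng.standard_normal(l0) + np.sign(rng.standard_normal(l0))
    return D0 @ C0, D0


class TestKSVD:
    def test_planted_recovery(self):
        X, D0 = planted_dictionary(0)
        result = clf.ksvd(X, 20, 3, iters=30, seed=0)
        corr = np.abs(result.atoms.T @ D0)
        recovered = sum(corr[:, j].max() > 0.95 for j in range(20))
        assert recovered >= 16  # >= 80 %

    def test_objective_non_increasing(self):
        X, _ = planted_dictionary(1, n=400)
        result = clf.ksvd(X, 15, 3, iters=10, seed=1)
        assert np.all(np.diff(result.objective_trace) <= 1e-9)

    def test_unit_norm_atoms(self):
        X, _ = planted_dictionary(2, n=300)
        result = clf.ksvd(X, 10, 3, iters=5, seed=2)
        assert np.allclose(np.linalg.norm(result.atoms, axis=0), 1.0, atol=1e-8)

    def test_square_unconstrained_limit(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((8, 8))
        result = clf.ksvd(X, 8, 8, iters=10, seed=3)
        codes = clf._omp_codes(result.atoms, X, 8)
        err = np.linalg.norm(X - result.atoms @ codes) / np.linalg.norm(X)
        assert err < 1e-6

    def test_too_many_atoms(self):
        with pytest.raises(ValueError):
            clf.ksvd(np.zeros((4, 5)), 6, 2)


def rotated_realm_task(seed, d=10):
    rng = np.random.default_rng(seed)
    means = rng.standard_normal((3, d)) * 4
    Xs = np.vstack([means[c] + rng.standard_normal((40, d)) for c in range(3)])
    ys = np.repeat(np.arange(3), 40)
    R = np.eye(d)
    for a, b in [(0, 1), (2, 3)]:
        th = np.deg2rad(40)
        Rp = np.eye(d)
        Rp[a, a] = np.cos(th)
        Rp[a, b] = -np.sin(th)
        Rp[b, a] = np.sin(th)
        Rp[b, b] = np.cos(th)
        R = R @ Rp
    shift = rng.standard_normal(d) * 4
    Xt = np.vstack(
        [(means[c] + rng.standard_normal((20, d))) @ R.T + shift for c in range(3)]
    )
    yt = np.repeat(np.arange(3), 20)
    return Xs.T, ys, Xt.T, yt


class TestRRSRC:
    def test_projections_orthonormal(self):
        Xs, ys, Xt, yt = rotated_realm_task(0)
        lab = np.concatenate([np.where(yt == c)[0][:3] for c in range(3)])
        model = clf.rrsrc_fit(Xs, ys, Xt[:, lab], yt[lab], d_sub=5, seed=0)
        for M in (model.source_projection, model.target_projection):
            assert np.allclose(M @ M.T, np.eye(5), atol=1e-8)

    def test_laplacian_rows_sum_to_zero(self):
        Xs, ys, Xt, yt = rotated_realm_task(1)
        lab = np.concatenate([np.where(yt == c)[0][:3] for c in range(3)])
        model = clf.rrsrc_fit(Xs, ys, Xt[:, lab], yt[lab], d_sub=4, seed=1)
        assert np.allclose(model.source_laplacian.sum(axis=1), 0.0, atol=1e-10)
        assert np.allclose(model.target_laplacian.sum(axis=1), 0.0, atol=1e-10)

    def test_pca_limit(self):
        # with an empty locality graph the projection solves the pure
        # variance-maximization problem, i.e. spans the PCA subspace
        rng = np.random.default_rng(2)
        basis = np.linalg.qr(rng.standard_normal((8, 8)))[0]
        spectrum = np.array([5.0, 3.0, 0.1, 0.05, 0.04, 0.03, 0.02, 0.01])
        Z = basis @ np.diag(spectrum) @ rng.standard_normal((8, 300))
        Z = Z - Z.mean(axis=1, keepdims=True)
        M = clf._projection_from_graph(Z, np.zeros((300, 300)), 1.0, 2)
        # compare with top-2 PCA directions via principal angles
        u, s, _ = np.linalg.svd(Z, full_matrices=False)
        pca_basis = u[:, :2]
        cosines = np.linalg.svd(M @ pca_basis, compute_uv=False)
        assert np.all(cosines > 1 - 1e-6)

    def test_domain_adaptation_beats_source_only(self):
        accs, base = [], []
        for seed in range(10):
            Xs, ys, Xt, yt = rotated_realm_task(seed)
            lab = np.concatenate([np.where(yt == c)[0][:3] for c in range(3)])
            test = np.setdiff1d(np.arange(yt.size), lab)
            model = clf.rrsrc_fit(
                Xs, ys, Xt[:, lab], yt[lab], d_sub=5, alpha_reg=1.0, seed=seed
            )
            preds = np.array([clf.rrsrc_classify(model, Xt[:, j]) for j in test])
            accs.append(np.mean(preds == yt[test]))
            bd = clf.ksvd_per_class(Xs, ys, atoms_per_class=10, l0=3, seed=seed)
            bp = np.array(
                [clf.src_classify(bd, np.unique(ys), Xt[:, j]) for j in test]
            )
            base.append(np.mean(bp == yt[test]))
        assert np.median(accs) >= 0.85
        assert np.median(accs) > np.median(base)

    def test_scaling_invariance_without_centering(self):
        Xs, ys, Xt, yt = rotated_realm_task(3)
        lab = np.concatenate([np.where(yt == c)[0][:3] for c in range(3)])
        model = clf.rrsrc_fit(
            Xs, ys, Xt[:, lab], yt[lab], d_sub=5, center=False, seed=3
        )
        rng = np.random.default_rng(4)
        for j in rng.choice(yt.size, 5, replace=False):
            z = Xt[:, j]
            assert clf.rrsrc_classify(model, z) == clf.rrsrc_classify(model, 7.3 * z)

    def test_huge_ridge_zeroes_code(self):
        Xs, ys, Xt, yt = rotated_realm_task(5)
        lab = np.concatenate([np.where(yt == c)[0][:3] for c in range(3)])
        model = clf.rrsrc_fit(Xs, ys, Xt[:, lab], yt[lab], d_sub=5, seed=5)
        code = clf._ridge_code(
            model.dictionary.atoms, model.target_projection @ Xt[:, 0], 1e18
        )
        assert np.allclose(code, 0.0, atol=1e-12)
        with pytest.raises(ValueError):
            clf._class_residual_label(
                model.dictionary.atoms,
                model.dictionary.class_index,
                model.classes,
                model.target_projection @ Xt[:, 0],
                np.zeros_like(code),
            )

    def test_missing_target_class_rejected(self):
        Xs, ys, Xt, yt = rotated_realm_task(6)
        only_c0 = np.where(yt == 0)[0][:3]
        with pytest.raises(ValueError):
            clf.rrsrc_fit(Xs, ys, Xt[:, only_c0], yt[only_c0], d_sub=4)


class TestSAE:
    def test_kl_zero_at_target(self):
        assert np.allclose(clf.kl_sparsity(0.2, np.full(5, 0.2)), 0.0)

    def test_kl_nonnegative(self):
        rng = np.random.default_rng(0)
        vals = clf.kl_sparsity(0.05, rng.uniform(0.01, 0.99, 100))
        assert np.all(vals >= 0)

    def test_loss_decreases_over_training(self):
        rng = np.random.default_rng(1)
        X = rng.random((150, 10))
        model = clf.sae_train(X, clf.SAEConfig(hidden=8, epochs=200, seed=1))
        assert model.loss_trace[-1] < model.loss_trace[0]

    def test_reconstruction_beats_untrained(self):
        rng = np.random.default_rng(2)
        X = rng.random((120, 8))
        cfg = clf.SAEConfig(hidden=6, epochs=100, seed=2)
        trained = clf.sae_train(X, cfg)
        untrained = clf.sae_train(X, dataclasses.replace(cfg, epochs=1))
        err_t = np.mean((clf.sae_reconstruct(trained, X) - X) ** 2)
        err_u = np.mean((clf.sae_reconstruct(untrained, X) - X) ** 2)
        assert err_t < err_u

    def test_loss_at_least_reconstruction(self):
        rng = np.random.default_rng(3)
        X = rng.random((60, 5))
        model = clf.sae_train(X, clf.SAEConfig(hidden=4, epochs=20, seed=3))
        recon = np.mean(
            np.sum((clf.sae_reconstruct(model, X) - X) ** 2, axis=1)
        )
        assert model.loss_trace[-1] >= recon - 1e-9

    def test_invalid_sparsity_target(self):
        with pytest.raises(ValueError):
            clf.SAEConfig(sparsity_target=1.5)


class TestGWOSVC:
    @staticmethod
    def circles(seed=0, n=100):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, 2 * np.pi, 2 * n)
        r = np.concatenate(
            [1 + 0.1 * rng.standard_normal(n), 3 + 0.1 * rng.standard_normal(n)]
        )
        X = np.c_[r * np.cos(theta), r * np.sin(theta)]
        return X, np.array([0] * n + [1] * n)

    def test_nonlinear_benchmark(self):
        from sklearn.svm import LinearSVC

        X, y = self.circles()
        model, c, g = clf.gwo_svc_tune(X, y, wolves=8, iters=8, seed=0)
        assert model.score(X, y) >= 0.95
        linear = LinearSVC().fit(X, y)
        assert linear.score(X, y) <= 0.6

    def test_params_in_bounds(self):
        X, y = self.circles(seed=1)
        _, c, g = clf.gwo_svc_tune(X, y, wolves=6, iters=5, seed=1)
        assert 1e-3 <= c <= 1e3 and 1e-3 <= g <= 1e3

    def test_determinism(self):
        X, y = self.circles(seed=2)
        _, c1, g1 = clf.gwo_svc_tune(X, y, wolves=6, iters=5, seed=2)
        _, c2, g2 = clf.gwo_svc_tune(X, y, wolves=6, iters=5, seed=2)
        assert c1 == c2 and g1 == g2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            clf.gwo_svc_tune(np.zeros((10, 2)), np.zeros(10))


class TestMetrics:
    def test_hand_computed_table(self):
        y_true = [1] * 55 + [0] * 45
        y_pred = [1] * 50 + [0] * 5 + [0] * 40 + [1] * 5
        report = clf.compute_metrics(y_true, y_pred, classes=[0, 1])
        pos = report.per_class[1]
        assert (pos["tp"], pos["tn"], pos["fp"], pos["fn"]) == (50, 40, 5, 5)
        assert pos["sensitivity"] == pytest.approx(100 * 50 / 55)
        assert pos["specificity"] == pytest.approx(100 * 40 / 45)
        assert report.accuracy == pytest.approx(90.0)

    def test_perfect_prediction(self):
        report = clf.compute_metrics([0, 1, 2, 1], [0, 1, 2, 1])
        assert report.accuracy == 100.0
        assert report.sensitivity == 100.0
        assert report.specificity == 100.0

    def test_all_positive_predictor(self):
        y_true = [1] * 50 + [0] * 50
        report = clf.compute_metrics(y_true, [1] * 100, classes=[0, 1])
        pos = report.per_class[1]
        assert pos["sensitivity"] == 100.0
        assert pos["specificity"] == 0.0
        assert report.accuracy == 50.0

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 3, 40)
        y_pred = rng.integers(0, 3, 40)
        report = clf.compute_metrics(y_true, y_pred)
        for c in report.classes:
            table = report.per_class[c]
            assert table["tp"] + table["tn"] + table["fp"] + table["fn"] == 40

    def test_accuracy_exact_fraction(self):
        y_true = np.array([0, 0, 1, 1, 2])
        y_pred = np.array([0, 1, 1, 1, 0])
        report = clf.compute_metrics(y_true, y_pred)
        assert report.accuracy == pytest.approx(100 * 3 / 5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            clf.compute_metrics([], [])
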