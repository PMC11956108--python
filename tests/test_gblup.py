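import numpy as np
import pytest
from scipy import linalg

from hybridgp.gblup import (
    KernelSet,
    MixedModelFit,
    TrainTestSplit,
    build_kernel,
    predict_blup,
    reml_fit,
)


def restricted_loglik_direct(v, y, X, Ks):
    """Independent restricted log-likelihood (direct formula, no reuse)."""
    n, p = X.shape
    V = v[-1] * np.eye(n)
    for vk, K in zip(v[:-1], Ks):
        V = V + vk * K
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (
        (n - p) * np.log(2 * np.pi)
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + r @ Vi @ r
    )


def em_reml_single_kernel(y, X, K, n_iter=8000):
    """Independent EM-REML for V = phi K + sigma I (classic EM updates)."""
    n, p = X.shape
    vy = y.var()
    phi, sig = vy / 2, vy / 2
    for _ in range(n_iter):
        V = phi * K + sig * np.eye(n)
        Vi = np.linalg.inv(V)
        P = Vi - Vi @ X @ np.linalg.solve(X.T @ Vi @ X, X.T @ Vi)
        Py = P @ y
        phi = phi + (phi**2 / n) * (Py @ (K @ Py) - np.sum(P * K))
        sig = sig + (sig**2 / n) * (Py @ Py - np.trace(P))
        phi, sig = max(phi, 1e-12), max(sig, 1e-12)
    return phi, sig


class TestBuildKernel:
    def test_identity(self):
        np.testing.assert_allclose(build_kernel(np.eye(3), 3), np.eye(3) / 3)

    def test_single_column(self, rng):
        w = rng.standard_normal((5, 1))
        np.testing.assert_allclose(build_kernel(w, 1), w @ w.T)

    def test_psd(self, rng):
        K = build_kernel(rng.standard_normal((10, 50)), 50)
        assert linalg.eigvalsh(K).min() >= -1e-10
        np.testing.assert_allclose(K, K.T)

    def test_zero_columns(self):
        with pytest.raises(ValueError):
            build_kernel(np.empty((4, 0)), 0)


class TestKernelSet:
    def test_validate_rejects_non_psd(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="PSD"):
            KernelSet(["bad"], [K]).validate()

    def test_validate_rejects_asymmetric(self):
        K = np.array([[1.0, 0.5], [0.0, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            KernelSet(["bad"], [K]).validate()

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            KernelSet(["a", "b"], [np.eye(3), np.eye(4)])


class TestRemlFit:
    def test_zero_residual_limit(self, rng):
        n = 30
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([2.0, -1.0])
        K = build_kernel(rng.standard_normal((n, 20)), 20)
        fit = reml_fit(y, X, KernelSet(["G"], [K]))
        vy = max(np.var(y), 1.0)
        assert all(v <= 1e-6 * vy for v in fit.variance_components.values())
        np.testing.assert_allclose(fit.beta, [2.0, -1.0], atol=1e-4)

    def test_balanced_anova_closed_form(self):
        # one-way random effects, 10 groups x 6 replicates
        rng = np.random.default_rng(2024)
        q, r = 10, 6
        n = q * r
        groups = np.repeat(np.arange(q), r)
        a = rng.normal(0, np.sqrt(2.0), q)
        y = 1.0 + a[groups] + rng.normal(0, 1.0, n)
        Z = np.zeros((n, q))
        Z[np.arange(n), groups] = 1.0
        K = Z @ Z.T
        fit = reml_fit(y, np.ones((n, 1)), KernelSet(["grp"], [K]))
        ybar_i = y.reshape(q, r).mean(axis=1)
        msa = r * np.sum((ybar_i - y.mean()) ** 2) / (q - 1)
        mse = np.sum((y.reshape(q, r) - ybar_i[:, None]) ** 2) / (q * (r - 1))
        sigma_a = max((msa - mse) / r, 0.0)
        assert fit.variance_components["residual"] == pytest.approx(mse, abs=1e-5)
        assert fit.variance_components["grp"] == pytest.approx(sigma_a, abs=1e-5)

    def test_beats_brute_force_grid(self):
        rng = np.random.default_rng(5)
        n = 20
        K = build_kernel(rng.standard_normal((n, 15)), 15)
        L = np.linalg.cholesky(0.8 * K + 0.5 * np.eye(n) + 1e-10 * np.eye(n))
        y = 1.5 + L @ rng.standard_normal(n)
        X = np.ones((n, 1))
        fit = reml_fit(y, X, KernelSet(["G"], [K]))
        vy = y.var()
        grid = np.linspace(0.01 * vy, 3 * vy, 50)
        best_grid = max(
            restricted_loglik_direct(np.array([p, s]), y, X, [K])
            for p in grid
            for s in grid
        )
        assert fit.restricted_loglik >= best_grid - 1e-6

    def test_matches_em_reml(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 40
            K = build_kernel(rng.choice([-1.0, 1.0], size=(n, 30)), 30)
            L = np.linalg.cholesky(1.2 * K + 0.7 * np.eye(n))
            y = 2.0 + L @ rng.standard_normal(n)
            X = np.ones((n, 1))
            fit = reml_fit(y, X, KernelSet(["G"], [K]))
            phi_em, sig_em = em_reml_single_kernel(y, X, K)
            assert fit.variance_components["G"] == pytest.approx(phi_em, abs=1e-4)
            assert fit.variance_components["residual"] == pytest.approx(sig_em, abs=1e-4)

    def test_scaling_equivariance(self, rng):
        n = 50
        K = build_kernel(rng.standard_normal((n, 40)), 40)
        L = np.linalg.cholesky(K + 0.5 * np.eye(n))
        y = L @ rng.standard_normal(n)
        kernels = KernelSet(["G"], [K])
        f1 = reml_fit(y, None, kernels)
        f2 = reml_fit(10.0 * y, None, kernels)
        for lbl in ("G", "residual"):
            assert f2.variance_components[lbl] == pytest.approx(
                100.0 * f1.variance_components[lbl], rel=1e-5
            )
        assert f2.beta[0] == pytest.approx(10.0 * f1.beta[0], rel=1e-5, abs=1e-8)

    def test_rejects_missing_y(self, rng):
        n = 12
        K = np.eye(n)
        y = rng.standard_normal(n)
        y[3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            reml_fit(y, None, KernelSet(["G"], [K]))

    def test_too_small_n(self, rng):
        with pytest.raises(ValueError, match="at least 10"):
            reml_fit(rng.standard_normal(5), None, KernelSet(["G"], [np.eye(5)]))

    def test_serializes(self, rng):
        n = 15
        fit = reml_fit(rng.standard_normal(n), None, KernelSet(["G"], [np.eye(n)]))
        import json

        payload = json.loads(fit.to_json())
        assert set(payload) >= {"beta", "variance_components", "restricted_loglik"}


class TestPredictBlup:
    def _setup(self, rng, n=12, n2=3, phi=1.3, sig=0.4):
        K = build_kernel(rng.standard_normal((n, 25)), 25)
        V = phi * K + sig * np.eye(n)
        y = rng.multivariate_normal(np.full(n, 0.7), V)
        return K, V, y

    def test_zero_covariance_collapses_to_fixed_effect(self, rng):
        n, n2 = 10, 2
        K = np.eye(n + n2)
        K[n:, :n] = 0.0
        K[:n, n:] = 0.0
        kernels = KernelSet(["G"], [K])
        split = TrainTestSplit.from_kernels(kernels, np.arange(n), np.arange(n, n + n2))
        fit = MixedModelFit(
            beta=np.array([3.0]),
            variance_components={"G": 1.0, "residual": 0.5},
            restricted_loglik=0.0, converged=True, n_iter=1, grad_norm=0.0,
            kernel_labels=["G"],
        )
        pred = predict_blup(fit, split, rng.standard_normal(n))
        np.testing.assert_allclose(pred, 3.0)

    def test_joint_gaussian_conditional_mean(self):
        # brute-force oracle: partition the joint covariance directly
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, n2 = 12, 4
            phi, sig, mu = 1.3, 0.4, 0.7
            K, V, y = self._setup(rng, n=n, phi=phi, sig=sig)
            train = np.arange(n - n2)
            test = np.arange(n - n2, n)
            kernels = KernelSet(["G"], [K])
            split = TrainTestSplit.from_kernels(kernels, train, test)
            fit = MixedModelFit(
                beta=np.array([mu]),
                variance_components={"G": phi, "residual": sig},
                restricted_loglik=0.0, converged=True, n_iter=1, grad_norm=0.0,
                kernel_labels=["G"],
            )
            pred = predict_blup(fit, split, y[train])
            V11 = V[np.ix_(train, train)]
            V21 = V[np.ix_(test, train)] - sig * np.zeros((n2, n - n2))
            # off-diagonal blocks of V carry no residual term
            V21 = phi * K[np.ix_(test, train)]
            oracle = mu + V21 @ np.linalg.solve(V11, y[train] - mu)
            np.testing.assert_allclose(pred, oracle, rtol=1e-8, atol=1e-10)

    def test_noiseless_duplicate_recovers_observation(self, rng):
        n = 25
        W = rng.standard_normal((n, 40))
        Wa = np.vstack([W, W[:1]])  # duplicate individual 0 into the test set
        K = build_kernel(Wa, 40)
        u = rng.standard_normal(40) / np.sqrt(40)
        y_all = Wa @ u  # pure kernel signal, no residual noise
        kernels = KernelSet(["G"], [K])
        split = TrainTestSplit.from_kernels(kernels, np.arange(n), np.array([n]))
        fit = MixedModelFit(
            beta=np.array([0.0]),
            variance_components={"G": 1.0, "residual": 1e-10},
            restricted_loglik=0.0, converged=True, n_iter=1, grad_norm=0.0,
            kernel_labels=["G"],
        )
        pred = predict_blup(fit, split, y_all[:n])
        assert pred[0] == pytest.approx(y_all[0], abs=1e-3)

    def test_training_permutation_invariance(self, rng):
        n, n2 = 15, 3
        K, V, y = self._setup(rng, n=n + n2)
        kernels = KernelSet(["G"], [K])
        fit = MixedModelFit(
            beta=np.array([0.5]),
            variance_components={"G": 1.0, "residual": 0.3},
            restricted_loglik=0.0, converged=True, n_iter=1, grad_norm=0.0,
            kernel_labels=["G"],
        )
        train = np.arange(n)
        test = np.arange(n, n + n2)
        perm = rng.permutation(n)
        p1 = predict_blup(fit, TrainTestSplit.from_kernels(kernels, train, test), y[train])
        p2 = predict_blup(
            fit, TrainTestSplit.from_kernels(kernels, train[perm], test), y[train][perm]
        )
        np.testing.assert_allclose(p1, p2, atol=1e-10)

    def test_label_mismatch_rejected(self, rng):
        n = 12
        K = np.eye(n)
        kernels = KernelSet(["other"], [K])
        split = TrainTestSplit.from_kernels(kernels, np.arange(10), np.array([10, 11]))
        fit = MixedModelFit(
            beta=np.array([0.0]), variance_components={"G": 1.0, "residual": 1.0},
            restricted_loglik=0.0, converged=True, n_iter=1, grad_norm=0.0,
            kernel_labels=["G"],
        )
        with pytest.raises(ValueError, match="match"):
            predict_blup(fit, split, rng.standard_normal(10))
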