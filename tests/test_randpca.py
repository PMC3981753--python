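import numpy as np
import pytest

import snpca
from snpca import RandPCAConfig, choose_orientation, rand_eigen
from snpca.randpca import decompose_standardized, exact_standardized

from conftest import make_genotype_matrix, spiked_matrix


def corr(a, b):
    return np.corrcoef(a, b)[0, 1]


class TestRandEigen:
    def test_identity_operator(self):
        """An isotropic operator has every eigenvalue equal to 1."""
        rng = np.random.default_rng(0)
        evals, _ = rand_eigen(lambda b: b, n=5, k=2, extra=2, maxiter=3, rng=rng)
        np.testing.assert_allclose(evals, 1.0, atol=1e-10)

    def test_rank_one_operator(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(6)
        v *= np.sqrt(7.0) / np.linalg.norm(v)  # ||v||^2 = 7
        evals, evecs = rand_eigen(
            lambda b: np.outer(v, v @ b), n=6, k=1, extra=2, maxiter=2, rng=rng
        )
        assert evals[0] == pytest.approx(7.0, abs=1e-8)
        unit = v / np.linalg.norm(v)
        assert abs(corr(evecs[:, 0], unit)) == pytest.approx(1.0, abs=1e-8)

    def test_matches_full_eigendecomposition(self):
        """Top-10 of a 50x200 Gram matrix vs. brute-force eigh."""
        x = spiked_matrix(50, 200, seed=2, decay=0.85)
        evals, _ = rand_eigen(
            lambda b: x @ (x.T @ b), n=50, k=10, extra=10, maxiter=10,
            rng=np.random.default_rng(3),
        )
        full = np.sort(np.linalg.eigvalsh(x @ x.T))[::-1]
        np.testing.assert_allclose(evals[:10], full[:10], rtol=1e-6)

    def test_sketch_too_wide_rejected(self):
        with pytest.raises(ValueError, match="k\\+extra"):
            rand_eigen(lambda b: b, n=3, k=3, extra=2, maxiter=1,
                       rng=np.random.default_rng(0))

    def test_nonfinite_detected(self):
        bad = np.full((4, 4), np.inf)
        with pytest.raises(FloatingPointError, match="initial sketch"):
            rand_eigen(lambda b: bad @ b, n=4, k=1, extra=1, maxiter=1,
                       rng=np.random.default_rng(0))


class TestOrientation:
    @pytest.mark.parametrize(
        "n, p, expected",
        [(957, 14389, "columns"), (150000, 43049, "rows"), (64, 64, "columns")],
    )
    def test_auto_policy(self, n, p, expected):
        assert choose_orientation(n, p, "auto") == expected

    def test_explicit_passthrough(self):
        assert choose_orientation(10, 2, "columns") == "columns"
        assert choose_orientation(2, 10, "rows") == "rows"

    def test_rows_columns_equivalence_tall_matrix(self):
        """A 6x4 (n > p) input decomposes identically either way."""
        rng = np.random.default_rng(4)
        x = rng.standard_normal((6, 4))
        x -= x.mean(axis=0)
        res = {}
        for orient in ("rows", "columns"):
            cfg = RandPCAConfig(k=3, extra=1, maxiter=8, seed=1, orientation=orient)
            res[orient] = decompose_standardized(x, cfg)
        np.testing.assert_allclose(
            res["rows"].eigenvalues, res["columns"].eigenvalues, atol=1e-9
        )
        np.testing.assert_allclose(res["rows"].pcs_P, res["columns"].pcs_P, atol=1e-8)


class TestRandomizedPCA:
    def test_oracle_equivalence_decaying_spectrum(self, default_cfg):
        x = spiked_matrix(150, 250, seed=11)
        rand = decompose_standardized(x, default_cfg)
        exact = exact_standardized(x, k=10)
        np.testing.assert_allclose(rand.eigenvalues, exact.eigenvalues, rtol=1e-6)
        for j in range(10):
            assert abs(corr(rand.eigenvectors_U[:, j], exact.eigenvectors_U[:, j])) >= 0.999

    def test_orthonormal_U_and_pc_scaling(self, small_structured, default_cfg):
        g, _ = small_structured
        res = snpca.randomized_pca(g, default_cfg)
        gram = res.eigenvectors_U.T @ res.eigenvectors_U
        assert np.abs(gram - np.eye(res.k)).max() <= 1e-8
        p = g.n_variants
        expect = res.eigenvectors_U * np.sqrt(res.eigenvalues * (p - 1))
        np.testing.assert_allclose(res.pcs_P, expect, rtol=1e-6, atol=1e-12)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert res.eigenvalues.min() >= -1e-9

    def test_duplicate_samples_map_to_identical_pcs(self, small_structured):
        """Doubling the cohort by exact copies: each copy lands on its original."""
        g, _ = small_structured
        doubled = make_genotype_matrix(np.vstack([g.dosages, g.dosages]))
        cfg = RandPCAConfig(k=5, extra=5, maxiter=6, seed=2)
        res = snpca.randomized_pca(doubled, cfg)
        n = g.n_samples
        np.testing.assert_allclose(res.pcs_P[:n], res.pcs_P[n:], atol=1e-8)

    def test_rank_deficient_input(self):
        rng = np.random.default_rng(6)
        x = np.outer(rng.standard_normal(30), rng.standard_normal(40))
        x += np.outer(rng.standard_normal(30), rng.standard_normal(40))
        cfg = RandPCAConfig(k=5, extra=3, maxiter=5, seed=1)
        res = decompose_standardized(x, cfg)
        assert np.all(res.eigenvalues[2:] <= 1e-9 * res.eigenvalues[0])

    def test_seed_determinism_bit_identical(self, small_structured, default_cfg):
        g, _ = small_structured
        a = snpca.randomized_pca(g, default_cfg)
        b = snpca.randomized_pca(g, default_cfg)
        assert np.array_equal(a.pcs_P, b.pcs_P)
        assert np.array_equal(a.eigenvalues, b.eigenvalues)

    def test_sign_convention(self, small_structured, default_cfg):
        g, _ = small_structured
        res = snpca.randomized_pca(g, default_cfg)
        idx = np.argmax(np.abs(res.eigenvectors_U), axis=0)
        assert np.all(res.eigenvectors_U[idx, np.arange(res.k)] > 0)

    def test_accuracy_monotone_in_maxiter(self):
        """Mean subspace error over 5 seeds does not grow with more iterations."""
        x = spiked_matrix(80, 160, seed=21, decay=0.92)
        exact = exact_standardized(x, k=5)
        proj = exact.eigenvectors_U @ exact.eigenvectors_U.T
        iters = [0, 1, 3, 8]
        errs = []
        for maxiter in iters:
            per_seed = []
            for seed in range(5):
                cfg = RandPCAConfig(k=5, extra=2, maxiter=maxiter, seed=seed)
                u = decompose_standardized(x, cfg).eigenvectors_U
                per_seed.append(np.linalg.norm(u - proj @ u))
            errs.append(np.mean(per_seed))
        for a, b in zip(errs, errs[1:]):
            assert b <= a + 1e-9

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            RandPCAConfig(k=0)
        with pytest.raises(ValueError):
            RandPCAConfig(k=2, extra=-1)
        with pytest.raises(ValueError):
            RandPCAConfig(k=2, stand="zscore")
        with pytest.raises(ValueError, match="exceeds min"):
            decompose_standardized(
                np.zeros((4, 6)), RandPCAConfig(k=3, extra=3, maxiter=1)
            )


class TestExactPCA:
    def test_svd_and_eigen_routes_agree(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((30, 80))
        x -= x.mean(axis=0)
        sv = exact_standardized(x, k=10, method="svd")
        ei = exact_standardized(x, k=10, method="eigen")
        np.testing.assert_allclose(sv.eigenvalues, ei.eigenvalues, rtol=1e-9)
        np.testing.assert_allclose(sv.pcs_P, ei.pcs_P, atol=1e-8)

    def test_singular_values_scale_to_eigenvalues(self):
        """sigma^2 / (p-1) equals the reported covariance eigenvalues."""
        rng = np.random.default_rng(9)
        x = rng.standard_normal((25, 60))
        x -= x.mean(axis=0)
        res = exact_standardized(x, k=5)
        s = np.linalg.svd(x, compute_uv=False)[:5]
        np.testing.assert_allclose(res.eigenvalues, s**2 / (x.shape[1] - 1), rtol=1e-12)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((12, 20))
        x -= x.mean(axis=0)
        res = exact_standardized(x, k=12)
        sigma = np.sqrt(res.eigenvalues * (x.shape[1] - 1))
        recon = res.eigenvectors_U @ np.diag(sigma) @ res.loadings_V.T
        np.testing.assert_allclose(recon, x, atol=1e-8)

    def test_matches_sklearn_pca_on_centered_data(self):
        """Independent cross-check against scikit-learn's exact PCA."""
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(12)
        x = rng.standard_normal((40, 90))
        x -= x.mean(axis=0)
        ours = exact_standardized(x, k=5)
        ref = PCA(n_components=5, svd_solver="full").fit(x)
        # sklearn scales variances by 1/(n-1); we report the 1/(p-1) convention
        np.testing.assert_allclose(
            ours.eigenvalues * (x.shape[1] - 1) / (x.shape[0] - 1),
            ref.explained_variance_,
            rtol=1e-10,
        )
        for j in range(5):
            assert abs(corr(ours.pcs_P[:, j], ref.transform(x)[:, j])) == pytest.approx(
                1.0, abs=1e-10
            )


def test_population_structure_recovered(small_structured, default_cfg):
    """Three islands at fst=0.1 separate cleanly in the PC1-PC2 plane."""
    from sklearn.metrics import silhouette_score

    g, labels = small_structured
    res = snpca.randomized_pca(g, default_cfg)
    assert silhouette_score(res.pcs_P[:, :2], labels) > 0.5
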