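"""SVR mapping engine: residualization, fitting, permutation inference."""

import numpy as np
import pandas as pd
import pytest

from strokemap.svr import (
    MappingError,
    PermutationNull,
    SVRConfig,
    apply_nuisance,
    cluster_threshold,
    correct_lesion_volume,
    fit_svr,
    fwe_threshold,
    permutation_null,
    residualize,
    run_lsm,
)


class TestResidualize:
    def test_orthogonal_centered_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 2))
        y = rng.standard_normal(50)
        y -= y.mean()
        # orthogonalize y against [1, X]
        design = np.column_stack([np.ones(50), X])
        y -= design @ np.linalg.lstsq(design, y, rcond=None)[0]
        assert np.allclose(residualize(y, X), y, atol=1e-10)

    def test_exact_fit_gives_zero(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 3))
        y = X @ [1.0, -2.0, 0.5] + 4.0
        assert np.allclose(residualize(y, X), 0.0, atol=1e-10)

    def test_pseudoinverse_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 3))
        y = rng.standard_normal(40)
        design = np.column_stack([np.ones(40), X])
        expected = y - design @ (np.linalg.pinv(design) @ y)
        assert np.allclose(residualize(y, X), expected, atol=1e-10)

    def test_collinear_column_named(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 2))
        X = np.column_stack([X, X[:, 0]])
        with pytest.raises(MappingError, match="collinear"):
            residualize(rng.standard_normal(20), X)


class TestVolumeCorrection:
    def test_constant_volume_skipped_with_warning(self):
        F = np.ones((10, 3))
        y = np.arange(10.0)
        with pytest.warns(UserWarning):
            F2, y2 = correct_lesion_volume(F, y, np.full(10, 5.0), "both")
        assert np.array_equal(F2, F) and np.array_equal(y2, y)

    def test_proportional_behavior_fully_removed(self):
        rng = np.random.default_rng(4)
        vol = rng.uniform(1, 10, 30)
        y = 3.0 * vol + 2.0
        _, y2 = correct_lesion_volume(rng.random((30, 2)), y, vol, "behavior_only")
        assert np.allclose(y2, 0.0, atol=1e-10)

    def test_column_loop_oracle(self):
        rng = np.random.default_rng(5)
        F = rng.random((25, 4)) * 100
        vol = rng.uniform(1, 10, 25)
        F2, _ = correct_lesion_volume(F, rng.random(25), vol, "both")
        for j in range(4):
            assert np.allclose(F2[:, j], residualize(F[:, j], vol), atol=1e-10)

    def test_mode_none_identity(self):
        F = np.random.default_rng(6).random((12, 2))
        y = np.arange(12.0)
        F2, y2 = correct_lesion_volume(F, y, np.arange(12.0) + 1, "none")
        assert np.array_equal(F2, F) and np.array_equal(y2, y)


def test_apply_nuisance_equals_residualize():
    rng = np.random.default_rng(7)
    cov = rng.standard_normal((40, 3))
    y = rng.standard_normal(40)
    assert np.allclose(apply_nuisance(y, cov), residualize(y, cov))
    assert np.allclose(apply_nuisance(y, None), y)


class TestFitSVR:
    def test_constant_target_errors(self):
        X = np.random.default_rng(8).random((20, 5))
        with pytest.raises(MappingError):
            fit_svr(X, np.ones(20), SVRConfig())

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        X = (rng.random((40, 10)) < 0.3).astype(float)
        y = X @ rng.uniform(0, 1, 10) + 0.1 * rng.standard_normal(40)
        perm = rng.permutation(10)
        b1 = fit_svr(X, y, SVRConfig())
        b2 = fit_svr(X[:, perm], y, SVRConfig())
        assert np.allclose(b1[perm], b2, atol=1e-8)

    def test_unit_norm(self):
        rng = np.random.default_rng(10)
        X = rng.random((30, 6))
        y = rng.standard_normal(30)
        assert np.linalg.norm(fit_svr(X, y, SVRConfig())) == pytest.approx(1.0)

    def test_rbf_kernel_runs(self):
        rng = np.random.default_rng(11)
        X = (rng.random((30, 8)) < 0.4).astype(float)
        y = X[:, 0] * 2 + 0.2 * rng.standard_normal(30)
        beta = fit_svr(X, y, SVRConfig(kernel="rbf"))
        assert np.isfinite(beta).all()
        assert np.linalg.norm(beta) == pytest.approx(1.0)

    def test_too_few_patients(self):
        with pytest.raises(MappingError):
            fit_svr(np.ones((5, 2)), np.arange(5.0), SVRConfig())


class TestPermutationNull:
    def _data(self, seed=12, n=40, p=20):
        rng = np.random.default_rng(seed)
        X = (rng.random((n, p)) < 0.3).astype(float)
        y = 3.0 * X[:, 2] + 0.3 * rng.standard_normal(n)
        return X, y

    def test_determinism(self):
        X, y = self._data()
        cfg = SVRConfig(n_permutations=50, seed=42)
        b1, n1 = permutation_null(X, y, cfg)
        b2, n2 = permutation_null(X, y, cfg)
        assert np.array_equal(b1, b2)
        assert np.array_equal(n1.p_uncorrected, n2.p_uncorrected)
        assert np.array_equal(n1.perm_betas, n2.perm_betas)

    def test_plus_one_convention(self):
        X, y = self._data()
        cfg = SVRConfig(n_permutations=100, seed=1)
        _, null = permutation_null(X, y, cfg)
        # the strongly informative feature dominates every permutation
        assert null.p_uncorrected[2] == pytest.approx(1.0 / 101.0)
        assert np.all(null.p_uncorrected > 0) and np.all(null.p_uncorrected <= 1)

    def test_null_p_values_near_uniform(self):
        means = []
        for seed in (13, 14, 15):
            rng = np.random.default_rng(seed)
            X = (rng.random((60, 200)) < 0.3).astype(float)
            y = rng.standard_normal(60)  # independent of features
            cfg = SVRConfig(n_permutations=500, seed=seed)
            _, null = permutation_null(X, y, cfg)
            means.append(null.p_uncorrected.mean())
        assert 0.45 <= np.mean(means) <= 0.55


class TestFWE:
    def test_single_feature_corrected_equals_uncorrected(self):
        rng = np.random.default_rng(14)
        X = (rng.random((30, 1)) < 0.5).astype(float)
        y = 2.0 * X[:, 0] + 0.3 * rng.standard_normal(30)
        cfg = SVRConfig(n_permutations=200, seed=3)
        obs, null = permutation_null(X, y, cfg)
        fwe, _ = fwe_threshold(obs, null)
        assert fwe[0] == pytest.approx(null.p_uncorrected[0])

    def test_corrected_dominates_uncorrected(self):
        rng = np.random.default_rng(15)
        X = (rng.random((40, 15)) < 0.3).astype(float)
        y = 2.0 * X[:, 0] + 0.5 * rng.standard_normal(40)
        cfg = SVRConfig(n_permutations=200, seed=4)
        obs, null = permutation_null(X, y, cfg)
        fwe, _ = fwe_threshold(obs, null)
        assert np.all(fwe >= null.p_uncorrected - 1e-12)

    def test_counting_oracle(self):
        rng = np.random.default_rng(16)
        X = (rng.random((40, 8)) < 0.4).astype(float)
        y = X[:, 1] + 0.4 * rng.standard_normal(40)
        cfg = SVRConfig(n_permutations=100, seed=5)
        obs, null = permutation_null(X, y, cfg)
        fwe, surv = fwe_threshold(obs, null, fwe_p=0.05)
        for j in range(8):
            expected = (1 + np.sum(null.max_z_distribution >= null.z_observed[j])) / 101.0
            assert fwe[j] == pytest.approx(expected)
            assert surv[j] == (fwe[j] < 0.05)


class TestClusterThreshold:
    def _null_with_observed(self, obs, n_perm=399, seed=6):
        rng = np.random.default_rng(seed)
        p_feat = len(obs)
        perm = rng.uniform(0, 0.1, (n_perm, p_feat)).astype(np.float32)
        exceed = np.sum(perm >= obs[None, :], axis=0)
        p_unc = (1.0 + exceed) / (n_perm + 1.0)
        mu, sd = perm.mean(0), perm.std(0)
        return PermutationNull(
            p_uncorrected=p_unc,
            perm_betas=perm,
            n_permutations=n_perm,
            beta_mean=mu,
            beta_sd=sd,
            z_observed=(obs - mu) / sd,
            max_z_distribution=((perm - mu) / sd).max(1),
        )

    def test_connectivity_definitions(self):
        # two voxels touching only diagonally: one cluster at 26, two at 6
        idx = np.array([[1, 1, 1], [2, 2, 2], [5, 5, 5]])
        obs = np.array([1.0, 1.0, 0.0])
        null = self._null_with_observed(obs)
        t26, _ = cluster_threshold(
            obs, null, idx, (8, 8, 8), SVRConfig(connectivity=26, n_permutations=399)
        )
        t6, _ = cluster_threshold(
            obs, null, idx, (8, 8, 8), SVRConfig(connectivity=6, n_permutations=399)
        )
        assert len(t26) == 1 and t26["size"].iloc[0] == 2
        assert len(t6) == 2 and set(t6["size"]) == {1}

    def test_no_suprathreshold_empty_table(self):
        idx = np.array([[1, 1, 1], [2, 2, 2]])
        obs = np.array([0.0, 0.0])
        null = self._null_with_observed(obs)
        table, surviving = cluster_threshold(
            obs, null, idx, (8, 8, 8), SVRConfig(n_permutations=399)
        )
        assert len(table) == 0 and not surviving.any()


class TestRunLSM:
    def _inputs(self, seed=17, n=30, p=12):
        rng = np.random.default_rng(seed)
        X = rng.random((n, p)) * 50
        X[:, 0] = 0.0  # never damaged -> dropped by coverage
        comps = pd.DataFrame({"C1": X[:, 3] / 25 + 0.3 * rng.standard_normal(n)})
        vols = rng.uniform(1000, 9000, n)
        return X, comps, vols

    def test_coverage_drops_undamaged_features(self):
        X, comps, vols = self._inputs()
        res = run_lsm(
            "parcel", X, list(range(12)), comps,
            SVRConfig(n_permutations=50, seed=0), volumes=vols,
        )["C1"]
        assert 0 not in res.feature_ids
        assert len(res.feature_ids) == 11

    def test_deterministic_given_seed(self):
        X, comps, vols = self._inputs()
        cfg = SVRConfig(n_permutations=60, seed=9)
        r1 = run_lsm("parcel", X, list(range(12)), comps, cfg, volumes=vols)["C1"]
        r2 = run_lsm("parcel", X, list(range(12)), comps, cfg, volumes=vols)["C1"]
        assert np.array_equal(r1.beta, r2.beta)
        assert np.array_equal(r1.p_uncorrected, r2.p_uncorrected)
        assert np.array_equal(r1.survives, r2.survives)

    def test_unknown_level_rejected(self):
        X, comps, vols = self._inputs()
        with pytest.raises(MappingError):
            run_lsm("lobe", X, list(range(12)), comps, SVRConfig(n_permutations=20))
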