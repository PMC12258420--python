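import json

import numpy as np
import pandas as pd
import pytest

from mvatost import (
    CanonicalModel,
    DegenerateCovarianceError,
    EquivalenceSpec,
    MCConfig,
    PopulationModel,
    from_paired_differences,
    read_crossover_csv,
    read_differences_csv,
    synthesize_canonical,
    synthesize_paired_data,
)


class TestPairedReduction:
    def test_hand_computed_univariate_reduction(self):
        # mean of (0.1, 0.2, 0.3) is 0.2; s^2 = 0.01; var of the mean = s^2/3
        model = from_paired_differences(np.array([0.1, 0.2, 0.3]))
        assert model.theta_hat == pytest.approx([0.2])
        np.testing.assert_allclose(model.sigma_hat_mat, [[0.01 / 3]], rtol=1e-12)
        assert model.nu == 2
        assert model.m == 1

    def test_collinear_columns_raise_degeneracy(self):
        d = np.array([[0.0, 0.0], [0.2, 0.2], [-0.2, -0.2], [0.0, 0.0]])
        with pytest.raises(DegenerateCovarianceError):
            from_paired_differences(d)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.0, 0.2, size=(12, 3))
        m1 = from_paired_differences(d)
        m2 = from_paired_differences(d[rng.permutation(12)])
        assert m1.nu == m2.nu == 11
        np.testing.assert_allclose(m1.theta_hat, m2.theta_hat)
        np.testing.assert_allclose(m1.sigma_hat_mat, m2.sigma_hat_mat)

    def test_nu_override_for_design_specific_anova(self):
        d = np.random.default_rng(1).normal(size=(10, 2))
        assert from_paired_differences(d, nu=8).nu == 8

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            from_paired_differences(np.array([0.1, 0.2]))

    def test_n_not_exceeding_m_is_singular(self):
        d = np.random.default_rng(2).normal(size=(3, 3))
        with pytest.raises(DegenerateCovarianceError):
            from_paired_differences(d)

    def test_dataframe_columns_become_outcome_names(self):
        df = pd.DataFrame(
            np.random.default_rng(3).normal(size=(8, 2)), columns=["auc", "cmax"]
        )
        assert from_paired_differences(df).outcome_names == ("auc", "cmax")


class TestSynthesizeCanonical:
    def test_fixed_seed_is_deterministic(self):
        pop = PopulationModel(theta=[0.0, 0.1], sigma_mat=np.eye(2) * 0.01)
        a = synthesize_canonical(pop, nu=20, seed=42)
        b = synthesize_canonical(pop, nu=20, seed=42)
        np.testing.assert_array_equal(a.theta_hat, b.theta_hat)
        np.testing.assert_array_equal(a.sigma_hat_mat, b.sigma_hat_mat)
        assert a.nu == 20

    def test_nu_below_m_rejected(self):
        pop = PopulationModel(theta=np.zeros(3), sigma_mat=np.eye(3))
        with pytest.raises(DegenerateCovarianceError):
            synthesize_canonical(pop, nu=2, seed=0)

    def test_moments_match_population(self):
        # unbiasedness of theta_hat and Sigma_hat, and the marginal
        # chi-square law of nu * Sigma_hat_jj / Sigma_jj
        nu, n_rep = 12, 10_000
        sigma = np.array([[0.01, 0.006], [0.006, 0.009]])
        pop = PopulationModel(theta=[0.0, 0.0], sigma_mat=sigma)
        rng = np.random.default_rng(7)
        thetas = np.empty((n_rep, 2))
        covs = np.empty((n_rep, 2, 2))
        for i in range(n_rep):
            m = synthesize_canonical(pop, nu=nu, rng=rng)
            thetas[i] = m.theta_hat
            covs[i] = m.sigma_hat_mat
        se_theta = np.sqrt(np.diag(sigma) / n_rep)
        assert np.all(np.abs(thetas.mean(axis=0)) < 3 * se_theta)
        err = np.abs(covs.mean(axis=0) - sigma)
        se_cov = covs.std(axis=0, ddof=1) / np.sqrt(n_rep)
        assert np.all(err < 3 * se_cov)
        scaled = nu * covs[:, [0, 1], [0, 1]] / np.diag(sigma)  # ~ chi2_nu
        se_chi = np.sqrt(2 * nu / n_rep)
        assert np.all(np.abs(scaled.mean(axis=0) - nu) < 3 * se_chi)


class TestSynthesizePairedData:
    def test_fixed_seed_reproduces_table(self):
        a = synthesize_paired_data(5, [0.0, 0.1], np.eye(2), seed=3)
        b = synthesize_paired_data(5, [0.0, 0.1], np.eye(2), seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_clt_mean_recovery(self):
        n = 10_000
        d = synthesize_paired_data(n, [0.05, -0.05], np.eye(2), seed=11)
        m = from_paired_differences(d)
        assert np.all(np.abs(m.theta_hat - [0.05, -0.05]) < 3.0 / np.sqrt(n))

    def test_correlation_recovery(self):
        cov = np.array([[1.0, 0.9], [0.9, 1.0]])
        d = synthesize_paired_data(200, [0.0, 0.0], cov, seed=5)
        r = np.corrcoef(d.to_numpy(), rowvar=False)[0, 1]
        assert abs(r - 0.9) < 0.05

    @pytest.mark.parametrize("n", [50, 500, 5000])
    def test_composition_recovers_population(self, n):
        # error in theta and in n * Sigma_hat shrinks like 1/sqrt(n)
        cov = np.array([[0.04, 0.018], [0.018, 0.025]])
        theta = np.array([0.02, -0.01])
        d = synthesize_paired_data(n, theta, cov, seed=n)
        m = from_paired_differences(d)
        assert m.nu == n - 1
        tol = 3 * np.sqrt(np.diag(cov) / n)
        assert np.all(np.abs(m.theta_hat - theta) < tol)
        assert np.linalg.norm(n * m.sigma_hat_mat - cov) < 1.5 / np.sqrt(n)

    def test_non_pd_within_cov_rejected(self):
        with pytest.raises(DegenerateCovarianceError):
            synthesize_paired_data(10, [0.0, 0.0], [[1.0, 1.0], [1.0, 1.0]], seed=0)


class TestValidation:
    def test_alpha_outside_range_rejected(self):
        with pytest.raises(ValueError):
            EquivalenceSpec(alpha=0.6)
        with pytest.raises(ValueError):
            EquivalenceSpec(c=-0.1)

    def test_canonical_model_shape_mismatch(self):
        with pytest.raises(ValueError):
            CanonicalModel(theta_hat=[0.1, 0.2], sigma_hat_mat=[[0.01]], nu=5)

    def test_mcconfig_validation(self):
        with pytest.raises(ValueError):
            MCConfig(n_wishart_draws=0)


class TestIO:
    def test_json_round_trip(self, tmp_path):
        model = CanonicalModel(
            theta_hat=[0.05, -0.02],
            sigma_hat_mat=[[0.004, 0.001], [0.001, 0.003]],
            nu=19,
            outcome_names=("auc", "cmax"),
        )
        p = tmp_path / "model.json"
        model.to_json(p)
        back = CanonicalModel.from_json(p)
        np.testing.assert_allclose(back.theta_hat, model.theta_hat)
        np.testing.assert_allclose(back.sigma_hat_mat, model.sigma_hat_mat)
        assert back.nu == 19 and back.outcome_names == ("auc", "cmax")
        assert json.loads(model.to_json())["nu"] == 19

    def test_wide_csv_reader(self, tmp_path):
        d = synthesize_paired_data(6, [0.0, 0.1], np.eye(2) * 0.04, seed=1)
        p = tmp_path / "wide.csv"
        d.to_csv(p, index=False)
        back = read_differences_csv(p)
        np.testing.assert_allclose(back.to_numpy(), d.to_numpy())

    def test_long_csv_reader_pairs_and_logs(self, tmp_path):
        rows = []
        raw = {"s1": (100.0, 80.0), "s2": (90.0, 90.0), "s3": (110.0, 100.0)}
        for subj, (t_val, r_val) in raw.items():
            rows.append((subj, "T", "auc", t_val))
            rows.append((subj, "R", "auc", r_val))
        df = pd.DataFrame(rows, columns=["subject", "treatment", "outcome", "value"])
        p = tmp_path / "long.csv"
        df.to_csv(p, index=False)
        wide = read_crossover_csv(p)
        expected = sorted(np.log(t) - np.log(r) for t, r in raw.values())
        np.testing.assert_allclose(sorted(wide["auc"]), expected)

    def test_long_csv_reader_rejects_unpaired(self, tmp_path):
        df = pd.DataFrame(
            [("s1", "T", "auc", 1.0)], columns=["subject", "treatment", "outcome", "value"]
        )
        p = tmp_path / "bad.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValueError):
            read_crossover_csv(p)
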