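import numpy as np
import pytest

import triadcausal as tc
from triadcausal import sem


@pytest.fixture(scope="module")
def catalog():
    return tc.enumerate_models()


class TestCatalog:
    def test_ten_models_with_anchored_identities(self, catalog):
        assert len(catalog) == 10
        by_id = {m.model_id: m for m in catalog}
        assert set(by_id[4].edges) == {("SNP", "MET"), ("MET", "LIP")}
        assert by_id[4].df == 1
        assert set(by_id[8].edges) == {("SNP", "LIP"), ("LIP", "MET")}
        assert by_id[8].df == 1
        assert set(by_id[10].edges) == {("SNP", "MET"), ("SNP", "LIP")}
        assert by_id[10].df == 1

    def test_exactly_seven_testable(self, catalog):
        testable = [m for m in catalog if m.df >= 1]
        assert len(testable) == 7
        assert {m.model_id for m in testable} == set(range(4, 11))
        saturated = [m for m in catalog if m.df == 0]
        assert {m.model_id for m in saturated} == {1, 2, 3}

    def test_snp_always_exogenous(self, catalog):
        for m in catalog:
            assert all(child != "SNP" for _, child in m.edges)

    def test_edge_into_snp_rejected(self):
        with pytest.raises(ValueError, match="exogenous"):
            sem.PathModel(99, (("MET", "SNP"),))

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            sem.PathModel(99, (("MET", "LIP"), ("LIP", "MET")))

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            tc.get_model(11)


class TestImpliedCovariance:
    def test_no_paths_identity(self):
        sigma = tc.implied_covariance(10, [0.0, 0.0, 1.0, 1.0, 1.0])
        np.testing.assert_allclose(sigma, np.eye(3))

    def test_chain_model_hand_matrix(self):
        sigma = tc.implied_covariance(4, [1.0, 1.0, 1.0, 1.0, 1.0])
        expected = np.array([[1, 1, 1], [1, 2, 2], [1, 2, 3]], dtype=float)
        np.testing.assert_allclose(sigma, expected)

    def test_pleiotropy_covariance_is_path_product(self):
        a, b, var_s = 0.4, 0.7, 0.42
        sigma = tc.implied_covariance(10, [a, b, var_s, 1.0, 1.0])
        assert sigma[1, 2] == pytest.approx(a * b * var_s)

    def test_matches_monte_carlo_forward_simulation(self):
        n = 200_000
        for model_id, coeffs in [
            (4, {"SNP->MET": 0.3, "MET->LIP": 0.5}),
            (10, {"SNP->MET": 0.4, "SNP->LIP": 0.6}),
        ]:
            spec = tc.TrueModelSpec(model_id, coeffs, maf=0.3, seed=model_id)
            df = tc.simulate_triad(spec, n)
            model = tc.get_model(model_id)
            theta = [coeffs[f"{p}->{c}"] for p, c in model.edges]
            theta += [2 * 0.3 * 0.7, 1.0, 1.0]
            sigma = tc.implied_covariance(model, theta)
            S = df.cov().to_numpy()
            mc_se = (np.abs(sigma) + 1.0) * np.sqrt(2.0 / n)
            assert np.all(np.abs(S - sigma) < 3 * mc_se)

    def test_wrong_parameter_count_rejected(self):
        with pytest.raises(ValueError, match="entries"):
            tc.implied_covariance(4, [0.1, 0.2, 1.0])


class TestFit:
    @pytest.mark.parametrize("model_id", range(4, 11))
    def test_self_consistency_on_population_sigma(self, model_id):
        model = tc.get_model(model_id)
        rng = np.random.default_rng(model_id)
        theta0 = np.concatenate(
            [rng.uniform(0.2, 0.6, len(model.edges)), rng.uniform(0.5, 2.0, 3)]
        )
        sigma0 = tc.implied_covariance(model, theta0)
        fit = tc.fit_model(model, sigma0, n=2000)
        assert fit.converged
        assert fit.chi2 < 1e-6
        np.testing.assert_allclose(fit.theta_hat, theta0, atol=1e-4)
        assert fit.p == pytest.approx(1.0, abs=1e-6)

    def test_saturated_models_reach_zero_discrepancy(self, rng):
        X = rng.standard_normal((300, 3))
        S = np.cov(X, rowvar=False)
        for model_id in (1, 2, 3):
            fit = tc.fit_model(model_id, S, n=300)
            assert fit.f_min < 1e-9
            assert fit.df == 0
            np.testing.assert_allclose(fit.implied_sigma, S, atol=1e-5)

    def test_markov_equivalent_models_share_likelihood(self):
        rng = np.random.default_rng(55)
        for _ in range(50):
            A = rng.standard_normal((3, 3))
            S = A @ A.T + 0.5 * np.eye(3)
            fmins = [tc.fit_model(mid, S, n=500).f_min for mid in (1, 2, 3)]
            assert max(fmins) - min(fmins) < 1e-8

    def test_chi2_scale_invariant(self, mediation_data):
        S = mediation_data.cov().to_numpy()
        D = np.diag([1.0, 3.7, 0.2])  # rescale MET and LIP
        fit1 = tc.fit_model(4, S, 2000)
        fit2 = tc.fit_model(4, D @ S @ D, 2000)
        assert fit2.chi2 == pytest.approx(fit1.chi2, abs=1e-5)

    def test_reverse_mediation_discriminated(self):
        wins = 0
        for seed in range(200):
            spec = tc.TrueModelSpec(
                8, {"SNP->LIP": 0.3, "LIP->MET": 0.5}, maf=0.3, seed=seed
            )
            df = tc.simulate_triad(spec, 2000)
            model = tc.SemModel.from_dataframe(df)
            fit8 = model.fit(8)
            fit4 = model.fit(4)
            if fit8.p >= 0.05 and fit4.chi2 > fit8.chi2:
                wins += 1
        assert wins >= 180

    def test_non_positive_definite_s_rejected(self):
        S = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            tc.fit_model(4, S, 100)


class TestFitIndices:
    def test_perfect_fit_values(self):
        sigma = tc.implied_covariance(4, [0.3, 0.5, 1.0, 1.0, 1.0])
        fit = tc.fit_model(4, sigma, n=1797)
        assert fit.gfi == pytest.approx(1.0, abs=1e-6)
        assert fit.rmsea == pytest.approx(0.0, abs=1e-6)
        assert fit.bic == pytest.approx(-np.log(1797), abs=1e-4)
        assert fit.bic == pytest.approx(-7.49, abs=0.01)

    def test_rmsea_clamped_at_chi2_equal_df(self):
        fit = sem.SemFitResult(
            model=tc.get_model(4), theta_hat=np.ones(5),
            implied_sigma=np.eye(3), f_min=0.0005, chi2=1.0, df=1, p=0.3,
            n=2001, converged=True,
        )
        _, rmsea, _ = tc.fit_indices(fit, np.eye(3), 2001)
        assert rmsea == 0.0

    def test_gfi_decreases_as_misfit_grows(self):
        sigma0 = tc.implied_covariance(4, [0.3, 0.5, 1.0, 1.0, 1.0])
        gfis = []
        for eps in np.linspace(0.0, 0.4, 5):
            S = sigma0.copy()
            S[0, 2] += eps  # perturb the SNP-LIP covariance
            S[2, 0] += eps
            fit = tc.fit_model(4, S, 1000)
            gfis.append(fit.gfi)
        assert all(a >= b - 1e-9 for a, b in zip(gfis, gfis[1:]))
        assert gfis[-1] < gfis[0]


class TestSelection:
    def _fake_fit(self, model_id, p=0.5, gfi=0.99, rmsea=0.01, bic=-5.0):
        return sem.SemFitResult(
            model=tc.get_model(model_id), theta_hat=np.ones(5),
            implied_sigma=np.eye(3), f_min=0.0, chi2=0.5, df=1, p=p,
            n=1000, converged=True, gfi=gfi, rmsea=rmsea, bic=bic,
        )

    def test_single_admissible_model_selected(self):
        fits = [self._fake_fit(4, bic=-9.0)] + [
            self._fake_fit(mid, p=0.001) for mid in (5, 6, 7, 8, 9, 10)
        ]
        selection = tc.select_best_model(fits)
        assert selection.selected == 4

    def test_close_bics_select_nothing(self):
        fits = [self._fake_fit(4, bic=-9.0), self._fake_fit(8, bic=-8.5)]
        selection = tc.select_best_model(fits)
        assert selection.selected is None
        assert set(selection.admissible) == {4, 8}

    def test_two_unit_margin_is_sufficient(self):
        fits = [self._fake_fit(4, bic=-9.0), self._fake_fit(8, bic=-7.0)]
        assert tc.select_best_model(fits).selected == 4

    def test_empty_admissible_set(self):
        fits = [self._fake_fit(mid, p=0.001) for mid in range(4, 11)]
        assert tc.select_best_model(fits).selected is None

    def test_power_against_growing_direct_effect(self):
        # data truly from MET <- SNP -> LIP; Model 4 misfit grows with
        # the direct SNP->LIP path
        chi2s = []
        for direct in (0.1, 0.3, 0.5, 0.7):
            sigma = tc.implied_covariance(10, [0.4, direct, 0.42, 1.0, 1.0])
            chi2s.append(tc.fit_model(4, sigma, 2000).chi2)
        assert all(a < b for a, b in zip(chi2s, chi2s[1:]))
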