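import numpy as np
import pandas as pd
import pytest
from scipy import stats

import triadcausal as tc
from triadcausal import assoc
from triadcausal.reference_tables import GCKR_META_PUBLISHED, SNP_METABOLITE_ASSOCIATIONS


def make_covariates(n, rng, batches=("B1", "B2")):
    return pd.DataFrame(
        {
            "age": rng.integers(30, 75, n).astype(float),
            "sex": rng.integers(0, 2, n),
            "batch": rng.choice(list(batches), n),
        },
        index=[f"s{i}" for i in range(n)],
    )


class TestResidualize:
    def test_independent_trait_only_demeaned(self, rng):
        covs = make_covariates(500, rng)
        trait = pd.Series(rng.standard_normal(500), index=covs.index)
        resid = tc.residualize(trait, covs)
        # only the fitted covariate effects (all ~0) are removed
        assert np.corrcoef(resid, trait - trait.mean())[0, 1] > 0.99

    def test_perfectly_explained_trait_vanishes(self, rng):
        covs = make_covariates(200, rng)
        trait = 2.0 * covs["age"]
        resid = tc.residualize(trait, covs)
        assert np.abs(resid).max() < 1e-9

    def test_batch_shift_equalized(self, rng):
        covs = make_covariates(400, rng)
        trait = pd.Series(rng.standard_normal(400), index=covs.index)
        trait[covs["batch"] == "B2"] += 0.5
        resid = tc.residualize(trait, covs)
        means = resid.groupby(covs["batch"]).mean()
        assert abs(means["B1"] - means["B2"]) < 1e-10

    def test_rank_deficient_design_rejected(self, rng):
        covs = make_covariates(100, rng)
        covs["age2"] = covs["age"]
        with pytest.raises(ValueError, match="rank"):
            tc.residualize(pd.Series(np.ones(100), index=covs.index), covs)


class TestSpearmanScreen:
    def test_monotone_function_gives_unit_rho(self, rng):
        x = rng.standard_normal(200)
        mets = pd.DataFrame({"m": x})
        lips = pd.DataFrame({"TG": np.exp(3 * x)})
        results, sig = tc.spearman_screen({"A": (mets, lips), "B": (mets, lips)})
        assert results[0].rho["A"] == pytest.approx(1.0)
        assert sig == [("m", "TG")]

    def test_bonferroni_threshold_value(self):
        assert assoc.spearman_alpha() == pytest.approx(0.05 / 604)
        assert float(f"{assoc.spearman_alpha():.1e}") == pytest.approx(8.3e-5)

    def test_requires_significance_in_both_cohorts(self, rng):
        x = rng.standard_normal(500)
        mets_a = pd.DataFrame({"m": x})
        lips_a = pd.DataFrame({"TG": x + 0.1 * rng.standard_normal(500)})
        # cohort B: unrelated
        mets_b = pd.DataFrame({"m": rng.standard_normal(500)})
        lips_b = pd.DataFrame({"TG": rng.standard_normal(500)})
        _, sig = tc.spearman_screen(
            {"A": (mets_a, lips_a), "B": (mets_b, lips_b)}
        )
        assert sig == []

    def test_constant_vector_skipped_with_warning(self, rng):
        mets = pd.DataFrame({"m": np.ones(50)})
        lips = pd.DataFrame({"TG": rng.standard_normal(50)})
        with pytest.warns(UserWarning, match="constant"):
            results, sig = tc.spearman_screen({"A": (mets, lips)})
        assert results == [] and sig == []


class TestSnpTraitAssociation:
    def test_noiseless_recovery(self, rng):
        g = pd.Series(tc.simulate_genotypes(500, 0.3, seed=1), name="snp")
        trait = pd.Series(0.5 * g + 1e-8 * rng.standard_normal(500), name="y")
        res = tc.snp_trait_assoc(g, trait)
        assert res.beta == pytest.approx(0.5, abs=1e-6)

    def test_null_p_values_uniform(self, rng):
        g = pd.Series(tc.simulate_genotypes(2000, 0.3, seed=2))
        y = rng.standard_normal(2000)
        pvals = []
        for i in range(200):
            perm = pd.Series(rng.permutation(y), index=g.index)
            pvals.append(tc.snp_trait_assoc(g, perm).p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_generative_truth_recovered(self, big_mediation_data):
        df = big_mediation_data
        res = tc.snp_trait_assoc(df["SNP"], df["MET"])
        assert abs(res.beta - 0.3) < 3 * res.se

    def test_scale_equivariance(self, mediation_data):
        df = mediation_data
        r1 = tc.snp_trait_assoc(df["SNP"], df["LIP"])
        r2 = tc.snp_trait_assoc(df["SNP"], 2.0 * df["LIP"])
        assert r2.beta == pytest.approx(2 * r1.beta)
        assert r2.se == pytest.approx(2 * r1.se)
        assert r2.p == pytest.approx(r1.p)

    def test_monomorphic_snp_rejected(self, rng):
        g = pd.Series(np.ones(100))
        with pytest.raises(ValueError, match="monomorphic"):
            tc.snp_trait_assoc(g, pd.Series(rng.standard_normal(100)))


class TestMetaAnalysis:
    @staticmethod
    def _res(cohort, beta, se):
        return assoc.AssociationResult(cohort, "snp", "trait", beta, se, 0.5, 100)

    def test_symmetric_inputs(self):
        meta = tc.inverse_variance_meta(
            [self._res("A", 0.5, 0.1), self._res("B", 0.5, 0.1)]
        )
        assert meta.beta == pytest.approx(0.5)
        assert meta.se == pytest.approx(0.1 / np.sqrt(2))

    def test_hand_arithmetic(self):
        meta = tc.inverse_variance_meta(
            [self._res("A", 0.2, 0.1), self._res("B", 0.5, 0.2)]
        )
        # weights 100 and 25
        assert meta.beta == pytest.approx((100 * 0.2 + 25 * 0.5) / 125)
        assert meta.se == pytest.approx(1 / np.sqrt(125))

    def test_published_two_cohort_row_reproduced(self):
        rows = SNP_METABOLITE_ASSOCIATIONS.query("snp == 'rs1260326'")
        results = [
            self._res(r.cohort, r.beta, r.se) for r in rows.itertuples()
        ]
        meta = tc.inverse_variance_meta(results)
        assert abs(meta.beta - GCKR_META_PUBLISHED["beta"]) < 0.001
        assert abs(meta.se - GCKR_META_PUBLISHED["se"]) < 0.001

    def test_combined_se_below_each_input(self):
        meta = tc.inverse_variance_meta(
            [self._res("A", 0.1, 0.12), self._res("B", 0.3, 0.4)]
        )
        assert meta.se < 0.12

    def test_mismatched_outcomes_rejected(self):
        a = assoc.AssociationResult("A", "snp", "x", 0.1, 0.1, 0.5, 100)
        b = assoc.AssociationResult("B", "snp", "y", 0.1, 0.1, 0.5, 100)
        with pytest.raises(ValueError, match="mixed"):
            tc.inverse_variance_meta([a, b])


class TestTriadSelection:
    @staticmethod
    def _meta(snp, trait, p_meta, p_cohorts=(1e-3, 1e-3)):
        per = [
            assoc.AssociationResult(f"C{i}", snp, trait, 0.1, 0.02, p, 500)
            for i, p in enumerate(p_cohorts)
        ]
        return assoc.MetaAnalysisResult(0.1, 0.01, p_meta, per)

    def test_nominal_rule_blocks_single_cohort_failure(self):
        met = [self._meta("rs1", "m1", 1e-7, (1e-6, 0.06))]
        lip = [self._meta("rs1", "TG", 1e-3)]
        assert tc.select_triads(met, lip) == []

    def test_threshold_value(self):
        assert assoc.metabolite_meta_alpha() == pytest.approx(0.05 / 15402)

    def test_cross_product_unique(self):
        met = [self._meta("rs1", "m1", 1e-8), self._meta("rs1", "m2", 1e-8)]
        lip = [self._meta("rs1", "TG", 1e-3), self._meta("rs1", "TC", 0.04)]
        triads = tc.select_triads(met, lip)
        assert len(triads) == 4
        assert len({(t.snp, t.met, t.lip) for t in triads}) == 4

    def test_row_order_invariance(self):
        met = [self._meta("rs1", "m1", 1e-8), self._meta("rs2", "m2", 1e-8)]
        lip = [self._meta("rs1", "TG", 1e-3), self._meta("rs2", "TC", 1e-3)]
        a = tc.select_triads(met, lip)
        b = tc.select_triads(met[::-1], lip[::-1])
        assert [(t.snp, t.met, t.lip) for t in a] == [(t.snp, t.met, t.lip) for t in b]

    def test_planted_triad_recovered_across_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            spec = tc.TrueModelSpec(
                4, {"SNP->MET": 0.3, "MET->LIP": 0.5}, maf=0.3, seed=seed
            )
            met_meta, lip_meta = [], []
            for snp_idx in range(21):
                if snp_idx == 0:
                    frames = [tc.simulate_triad(spec, 1000, seed=1000 * seed + c)
                              for c in range(2)]
                else:
                    frames = []
                    for c in range(2):
                        g = tc.simulate_genotypes(1000, 0.3, seed=rng.integers(2**31))
                        frames.append(pd.DataFrame({
                            "SNP": g,
                            "MET": rng.standard_normal(1000),
                            "LIP": rng.standard_normal(1000),
                        }))
                met_res, lip_res = [], []
                name = f"rs{snp_idx}"
                for c, df in enumerate(frames):
                    met_res.append(tc.snp_trait_assoc(
                        df["SNP"], df["MET"], cohort=f"C{c}",
                        predictor=name, outcome="MET007"))
                    lip_res.append(tc.snp_trait_assoc(
                        df["SNP"], df["LIP"], cohort=f"C{c}",
                        predictor=name, outcome="TG"))
                met_meta.append(tc.inverse_variance_meta(met_res))
                lip_meta.append(tc.inverse_variance_meta(lip_res))
            triads = tc.select_triads(met_meta, lip_meta)
            if [(t.snp, t.met, t.lip) for t in triads] == [("rs0", "MET007", "TG")]:
                hits += 1
        assert hits >= 19


class TestAceHeritability:
    def test_pure_additive_boundary(self):
        panel = tc.simulate_twin_panel(2000, 2000, a2=1.0, c2=0.0, seed=1)
        est = tc.estimate_ace(panel)
        assert est.h2 > 0.95
        assert est.c2 < 0.05

    def test_no_additive_signal_hits_zero_boundary(self):
        panel = tc.simulate_twin_panel(2000, 2000, a2=0.0, c2=0.5, seed=2)
        est = tc.estimate_ace(panel)
        assert est.a2 < 0.05

    def test_recovery_with_falconer_cross_check(self):
        panel = tc.simulate_twin_panel(2000, 2000, a2=0.5, c2=0.2, seed=3)
        est = tc.estimate_ace(panel)
        assert abs(est.h2 - 0.5) < 0.05
        r_mz = np.corrcoef(panel.values("MZ").T)[0, 1]
        r_dz = np.corrcoef(panel.values("DZ").T)[0, 1]
        falconer = 2 * (r_mz - r_dz)
        assert abs(est.h2 - falconer) < 0.05

    def test_scale_invariance(self):
        panel = tc.simulate_twin_panel(500, 500, a2=0.4, c2=0.1, seed=4)
        est1 = tc.estimate_ace(panel)
        scaled = tc.TwinPanel(
            panel.pairs.assign(twin1=panel.pairs.twin1 * 37.5,
                               twin2=panel.pairs.twin2 * 37.5)
        )
        est2 = tc.estimate_ace(scaled)
        assert est2.h2 == pytest.approx(est1.h2, abs=1e-4)

    def test_minimum_pair_counts_enforced(self):
        panel = tc.simulate_twin_panel(10, 100, a2=0.4, c2=0.1, seed=5)
        with pytest.raises(ValueError, match="pairs"):
            tc.TwinAceModel(panel)
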