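"""FIML likelihood correctness, constrained fitting and likelihood-ratio tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pubertwin as pt
from pubertwin.model import Constraint, FamilyData, TwinACEModel, fiml_loglik, lrt
from pubertwin.paths import expected_cov, random_path_model
from tests.conftest import make_pair_data


def mvn_logpdf(y, mean, cov):
    return stats.multivariate_normal(mean=mean, cov=cov, allow_singular=False).logpdf(y)


class TestFimlLoglik:
    def test_complete_data_equals_direct_mvn_loglik(self, rng):
        truth = random_path_model(np.random.default_rng(0))
        data = make_pair_data(truth, 40, 40, seed=1)
        direct = 0.0
        for z in ("MZ", "DZ"):
            y = data.y[data.zygosity == z]
            S = expected_cov(truth, z)
            mu = np.tile(truth.means, 2)
            direct += mvn_logpdf(y, mu, S).sum()
        assert fiml_loglik(truth, data) == pytest.approx(direct, abs=1e-9)

    def test_single_observed_value_reduces_to_univariate_density(self):
        truth = pt.default_path_model()
        y = np.full((1, 8), np.nan)
        y[0, 0] = 0.3
        data = FamilyData(y, np.array(["MZ"]))
        v = truth.a[0] ** 2 + truth.c[0] ** 2 + truth.e[0] ** 2
        m = truth.means[0]
        expect = -0.5 * (np.log(2 * np.pi * v) + (0.3 - m) ** 2 / v)
        assert fiml_loglik(truth, data) == pytest.approx(expect, abs=1e-12)

    def test_missing_value_equals_marginalized_density(self):
        # drop phenotype 3 of twin 2: FIML must equal the density of the
        # explicitly marginalized 7-variate normal
        truth = random_path_model(np.random.default_rng(2))
        rng = np.random.default_rng(3)
        y = pt.draw_pair_phenotypes(truth, "DZ", 5, rng)
        y[:, 7] = np.nan
        data = FamilyData(y, np.array(["DZ"] * 5))
        keep = [0, 1, 2, 3, 4, 5, 6]
        S = expected_cov(truth, "DZ")[np.ix_(keep, keep)]
        mu = np.tile(truth.means, 2)[keep]
        direct = mvn_logpdf(y[:, keep], mu, S).sum()
        assert fiml_loglik(truth, data) == pytest.approx(direct, abs=1e-9)

    def test_invariant_to_family_and_twin_order(self):
        truth = random_path_model(np.random.default_rng(4))
        rng = np.random.default_rng(5)
        y = pt.draw_pair_phenotypes(truth, "MZ", 20, rng)
        y[::3, 6] = np.nan
        zyg = np.array(["MZ"] * 20)
        base = fiml_loglik(truth, FamilyData(y, zyg))
        perm = np.random.default_rng(6).permutation(20)
        assert fiml_loglik(truth, FamilyData(y[perm], zyg)) == pytest.approx(base, abs=1e-9)
        swapped = np.hstack([y[:, 4:], y[:, :4]])  # twins exchanged
        assert fiml_loglik(truth, FamilyData(swapped, zyg)) == pytest.approx(base, abs=1e-9)

    def test_gradient_matches_finite_differences(self, fitted_coupled):
        from scipy.optimize import approx_fprime

        model, _ = fitted_coupled
        pats = model._std_data._patterns
        theta = model.parameterization.pack(model._moment_start(model._std_data))
        num = approx_fprime(theta, lambda t: model._negloglik_and_grad(t, pats)[0], 1e-7)
        ana = model._negloglik_and_grad(theta, pats)[1]
        assert np.abs(num - ana).max() / (1 + np.abs(num).max()) < 1e-4


class TestFit:
    def test_parameter_recovery(self, fsh_truth, fitted_coupled):
        # one replicate: familiality (a2+c2, well identified) and e2 close to
        # truth; the A/C split individually is noisier at this sample size
        # and is checked as a mean over replicates in the acceptance suite
        _, res = fitted_coupled
        assert res.converged
        vc, true_vc = res.variance_components(), fsh_truth.variance_components()
        assert np.abs((vc["a2"] + vc["c2"]) - (true_vc["a2"] + true_vc["c2"])).max() < 0.2
        assert np.abs(vc["e2"] - true_vc["e2"]).max() < 0.2
        cs = res.change_stats()
        assert cs.r_ch == pytest.approx(0.5, abs=0.12)
        assert cs.rph_e == pytest.approx(cs.r_ch, abs=0.12)

    def test_loglik_at_truth_not_above_mle(self, fsh_truth, fitted_coupled):
        model, res = fitted_coupled
        assert res.loglik >= fiml_loglik(fsh_truth, model.data) - 1e-6

    def test_constrained_fit_never_beats_full(self, fitted_coupled):
        model, full = fitted_coupled
        for name in ("change_corr_zero", "rph_e_zero", "cross_trait_age12_zero"):
            con = model.fit(constraint=name, n_starts=1, seed=0, start_model=full.path_model)
            assert con.loglik <= full.loglik + 1e-6
            assert con.n_params == full.n_params - 1

    def test_constraint_enforced_at_solution(self, fitted_coupled):
        model, full = fitted_coupled
        con = model.fit(constraint="change_corr_zero", n_starts=1, seed=0,
                        start_model=full.path_model)
        # residual on the standardized scale is driven below 1e-8
        assert abs(pt.change_covariance(con.path_model)) < 1e-6

    def test_nonconvergence_is_flagged_not_silent(self):
        truth = pt.default_path_model()
        data = make_pair_data(truth, 4, 4, seed=9)
        res = TwinACEModel(data).fit(n_starts=1, seed=0, maxiter=2)
        assert res.converged is False

    def test_summary_reports_key_quantities(self, fitted_coupled):
        _, res = fitted_coupled
        text = res.summary()
        assert "log-likelihood" in text
        assert "change correlation" in text
        assert "hormone_age9" in text

    def test_results_export_round_trips_through_json(self, fitted_coupled):
        import json

        _, res = fitted_coupled
        d = json.loads(json.dumps(res.to_dict()))
        assert d["loglik"] == pytest.approx(res.loglik)
        assert d["change_stats"]["r_ch"] == pytest.approx(res.change_stats().r_ch)
        np.testing.assert_allclose(d["a"], res.path_model.a)


class TestLRT:
    def test_identical_logliks_give_zero_chi2_p_one(self, fitted_coupled):
        model, full = fitted_coupled
        clone = pt.TwinACEResults(
            model=model, path_model=full.path_model, loglik=full.loglik,
            n_params=full.n_params - 1, converged=True,
        )
        out = lrt(full, clone)
        assert out.chi2 == 0.0
        assert out.p == 1.0

    def test_chi2_quantile_maps_to_nominal_alpha(self, fitted_coupled):
        model, full = fitted_coupled
        c = pt.TwinACEResults(
            model=model, path_model=full.path_model,
            loglik=full.loglik - 3.841 / 2, n_params=full.n_params - 1, converged=True,
        )
        assert lrt(full, c).p == pytest.approx(0.05, abs=5e-4)

    def test_df_must_be_positive(self, fitted_coupled):
        _, full = fitted_coupled
        with pytest.raises(ValueError, match="fewer free parameters"):
            lrt(full, full)

    def test_power_against_a_true_coupling(self, fitted_coupled):
        model, full = fitted_coupled
        con = model.fit(constraint="change_corr_zero", n_starts=1, seed=0,
                        start_model=full.path_model)
        out = lrt(full, con)
        assert out.chi2 > 25
        assert out.p < 1e-6


class TestBivariateAge12:
    def test_recovers_pure_c_cross_trait_correlation(self):
        truth = pt.bivariate_age12_truth(r_cross=-0.47, component="c")
        data = make_pair_data(truth, 500, 500, seed=30)
        res = TwinACEModel(data).fit(n_starts=2, seed=0)
        cs = res.change_stats(target="age12_cross_trait")
        assert cs.r_ch == pytest.approx(-0.47, abs=0.1)
        assert cs.rph_c == pytest.approx(-0.47, abs=0.12)
        assert abs(cs.rph_a) + abs(cs.rph_e) < 0.15

    def test_cross_trait_lrt_rejects_under_coupling(self):
        truth = pt.bivariate_age12_truth(r_cross=-0.47, component="c")
        data = make_pair_data(truth, 300, 300, seed=31)
        m = TwinACEModel(data)
        full = m.fit(n_starts=2, seed=0)
        con = m.fit(constraint="cross_trait_age12_zero", n_starts=1, seed=0,
                    start_model=full.path_model)
        assert lrt(full, con).p < 1e-4

    def test_matches_four_variate_fit_with_occasion1_missing(self, small_cohort):
        from pubertwin.hormones import prepare_hormone_table

        cohort = small_cohort
        table = prepare_hormone_table(cohort.table, hormone="fsh")
        gm = cohort.gm_at_voxel((1, 1, 1))
        biv = TwinACEModel.from_table(table, gm_values=gm, occasions=(2,))
        res2 = biv.fit(n_starts=3, seed=0)
        # blank occasion 1 in the long model: same observed data
        table4 = table.copy()
        gm4 = gm.copy()
        occ1 = (table4["occasion"] == 1).to_numpy()
        table4.loc[occ1, "hormone"] = np.nan
        gm4[occ1] = np.nan
        quad = TwinACEModel.from_table(table4, gm_values=gm4, occasions=(1, 2))
        res4 = quad.fit(n_starts=3, seed=0)
        assert res4.loglik == pytest.approx(res2.loglik, abs=0.05)

    def test_bivariate_classmethod_builds_two_phenotype_model(self, small_cohort):
        from pubertwin.hormones import prepare_hormone_table

        cohort = small_cohort
        cohort.table = prepare_hormone_table(cohort.table, hormone="fsh")
        biv = TwinACEModel.bivariate_age12(cohort, voxel=(1, 1, 1))
        assert biv.p == 2
        assert biv.parameterization.n == 11  # 3x2 paths + 3 angles + 2 means


class TestConstraintNames:
    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown constraint"):
            Constraint.for_name("not_a_constraint", 4)

    def test_change_constraint_needs_longitudinal_model(self):
        with pytest.raises(ValueError, match="4-phenotype"):
            Constraint.for_name("change_corr_zero", 2)

    def test_component_constraint_targets(self):
        ch = Constraint.for_name("rph_e_zero", 4, "change")
        assert ch.kind == "comp_ch"
        a12 = Constraint.for_name("rph_e_zero", 4, "age12_cross_trait")
        assert (a12.kind, a12.i, a12.j) == ("comp_ij", 2, 3)
        biv = Constraint.for_name("rph_c_zero", 2)
        assert (biv.kind, biv.i, biv.j) == ("comp_ij", 0, 1)


class TestAgeCovariate:
    def test_recovers_induced_age_slope(self, small_cohort):
        # inject a linear age effect on the age-12 hormone mean and check the
        # means-model covariate picks it up (ages vary only a little within
        # an occasion, so the tolerance is wide)
        from pubertwin.hormones import prepare_hormone_table

        table = prepare_hormone_table(small_cohort.table, hormone="fsh")
        occ2 = table["occasion"] == 2
        slope = 2.0
        age_c = table.loc[occ2, "age"] - table.loc[occ2, "age"].mean()
        table.loc[occ2, "hormone"] = table.loc[occ2, "hormone"] + slope * age_c
        gm = small_cohort.gm_at_voxel((0, 0, 0))
        m = pt.TwinACEModel.from_table(table, gm_values=gm, age_effects=True)
        res = m.fit(n_starts=2, seed=0)
        assert res.path_model.age_slopes is not None
        assert res.path_model.age_slopes[2] == pytest.approx(slope, abs=1.0)


class TestFromTable:
    def test_long_table_assembly(self):
        table = pd.DataFrame(
            {
                "family_id": ["f1"] * 4 + ["f2"],
                "twin_id": ["f1_t1", "f1_t1", "f1_t2", "f1_t2", "f2_t1"],
                "zygosity": ["MZ"] * 4 + ["DZ"],
                "occasion": [1, 2, 1, 2, 1],
                "age": [9.1, 12.0, 9.1, 12.0, 9.3],
                "hormone": [0.1, 0.2, 0.3, 0.4, 0.5],
                "gm": [0.6, 0.55, 0.62, 0.57, 0.61],
            }
        )
        data = FamilyData.from_table(table, gm_col="gm")
        assert data.n_families == 2
        f1 = data.y[0]
        np.testing.assert_allclose(f1, [0.1, 0.6, 0.2, 0.55, 0.3, 0.62, 0.4, 0.57])
        f2 = data.y[1]
        assert np.isfinite(f2[:2]).all() and np.isnan(f2[2:]).all()

    def test_unknown_zygosity_rejected(self):
        with pytest.raises(ValueError, match="zygosity"):
            FamilyData(np.zeros((1, 8)), np.array(["OS"]))
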