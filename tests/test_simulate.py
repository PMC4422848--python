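"""Synthetic cohort generator: twin structure, censoring, dropout, round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pubertwin as pt
from pubertwin.paths import expected_cov
from pubertwin.simulate import (
    SimulationConfig,
    read_cohort,
    simulate_cohort,
    write_cohort,
)


def small_config(seed=0, **over):
    kw = dict(
        rng_seed=seed,
        n_mz_pairs=30,
        n_dz_pairs=30,
        n_singletons=4,
        grid_shape=(3, 3, 3),
        signal_cluster=[(1, 1, 1)],
        cluster_model=pt.plant_coupling(pt.default_path_model(), "e", 0.5),
        dropout_rate_occasion2=0.3,
    )
    kw.update(over)
    return SimulationConfig(**kw)


class TestDeterminismAndStructure:
    def test_same_seed_same_cohort(self):
        c1 = simulate_cohort(small_config(3))
        c2 = simulate_cohort(small_config(3))
        pd.testing.assert_frame_equal(c1.table, c2.table)
        assert np.array_equal(c1.voxel_data, c2.voxel_data, equal_nan=True)

    def test_different_seed_different_cohort(self):
        c1 = simulate_cohort(small_config(3))
        c2 = simulate_cohort(small_config(4))
        assert not np.array_equal(c1.voxel_data, c2.voxel_data, equal_nan=True)

    def test_pair_structure_and_zygosity_labels(self):
        cohort = simulate_cohort(small_config(1))
        sizes = cohort.table.groupby("family_id")["twin_id"].nunique()
        assert set(sizes.unique()) <= {1, 2}
        assert (sizes == 1).sum() == 4  # singletons
        assert set(cohort.table["zygosity"]) == {"MZ", "DZ"}
        pairs = cohort.pairs()
        assert len(pairs) == cohort.table["family_id"].nunique()
        assert all(p.rows["zygosity"].eq(p.zygosity).all() for p in pairs)

    def test_dropout_fraction_within_binomial_ci(self):
        cfg = small_config(5, n_mz_pairs=400, n_dz_pairs=400, n_singletons=0,
                           dropout_rate_occasion2=0.34)
        cohort = simulate_cohort(cfg)
        n_ind = cohort.table["twin_id"].nunique()
        n_occ2 = (cohort.table["occasion"] == 2).sum()
        missing = n_ind - n_occ2
        lo, hi = stats.binom.ppf([0.0025, 0.9975], n_ind, 0.34)
        assert lo <= missing <= hi

    def test_detection_limit_censoring_flags(self):
        # high limit: many censored; flagged days must have NaN levels
        cfg = small_config(6, detection_limit=0.6)
        cohort = simulate_cohort(cfg)
        t = cohort.table
        assert t["below_limit_day1"].any()
        assert t.loc[t["below_limit_day1"], "hormone_day1"].isna().all()
        assert t.loc[~t["below_limit_day1"], "hormone_day1"].notna().all()

    def test_raw_hormone_scale_is_left_skewed(self):
        cfg = small_config(7, n_mz_pairs=200, n_dz_pairs=200, n_singletons=0,
                           dropout_rate_occasion2=0.0, detection_limit=0.0)
        t = simulate_cohort(cfg).table
        raw = (t["hormone_day1"] / t["creatinine_day1"]).dropna()
        assert stats.skew(raw) > 0.5  # long right tail on the raw scale
        assert abs(stats.skew(np.log(raw))) < 0.3


class TestLatentFactorContracts:
    def test_common_environment_identical_within_pair(self):
        # with a=e~0 and c~1, phenotypes are (nearly) the shared C factor
        p4 = np.eye(4)
        truth = pt.PathModel(
            a=np.full(4, 1e-6), c=np.ones(4), e=np.full(4, 1e-6),
            R_g=p4, R_c=p4, R_e=p4,
        )
        x = pt.draw_pair_phenotypes(truth, "DZ", 50, np.random.default_rng(0))
        assert np.allclose(x[:, :4], x[:, 4:], atol=1e-4)

    def test_cross_twin_genetic_covariance_by_zygosity(self):
        one = np.eye(1)
        truth = pt.PathModel(a=[1.0], c=[1e-6], e=[1e-6], R_g=one, R_c=one, R_e=one)
        rng = np.random.default_rng(1)
        n = 5000
        for z, target in (("MZ", 1.0), ("DZ", 0.5)):
            x = pt.draw_pair_phenotypes(truth, z, n, rng)
            cov = np.cov(x[:, 0], x[:, 1])[0, 1]
            assert cov == pytest.approx(target, abs=4 / np.sqrt(n))

    def test_e_only_model_has_no_twin_resemblance(self):
        one = np.eye(1)
        truth = pt.PathModel(a=[1e-9], c=[1e-9], e=[1.0], R_g=one, R_c=one, R_e=one)
        rng = np.random.default_rng(2)
        for z in ("MZ", "DZ"):
            x = pt.draw_pair_phenotypes(truth, z, 2000, rng)
            assert abs(np.corrcoef(x[:, 0], x[:, 1])[0, 1]) < 0.05

    def test_twin_correlations_match_closed_form(self):
        # a2=0.6, c2=0.2, e2=0.2: rMZ = 0.8, rDZ = 0.5
        one = np.eye(1)
        truth = pt.PathModel(
            a=[np.sqrt(0.6)], c=[np.sqrt(0.2)], e=[np.sqrt(0.2)],
            R_g=one, R_c=one, R_e=one,
        )
        rng = np.random.default_rng(3)
        for z, target in (("MZ", 0.8), ("DZ", 0.5)):
            x = pt.draw_pair_phenotypes(truth, z, 2000, rng)
            assert np.corrcoef(x[:, 0], x[:, 1])[0, 1] == pytest.approx(target, abs=0.04)

    def test_cohort_covariance_matches_expected_cov(self):
        # in-cluster voxel + hormone phenotypes reproduce the ground-truth
        # pair covariance (no smoothing, no censoring, no assay noise)
        truth = pt.plant_coupling(pt.default_path_model(), "e", 0.5)
        cfg = small_config(
            9, n_mz_pairs=3000, n_dz_pairs=3000, n_singletons=0,
            dropout_rate_occasion2=0.0, smoothing_fwhm_voxels=0.0,
            assay_log_sd=0.0, detection_limit=0.0, cluster_model=truth,
        )
        cohort = simulate_cohort(cfg)
        t = cohort.table.copy()
        t["hormone"] = np.log(
            0.5 * (t.hormone_day1 / t.creatinine_day1 + t.hormone_day2 / t.creatinine_day2)
        )
        gm = cohort.gm_at_voxel((1, 1, 1))
        from pubertwin.model import FamilyData

        data = FamilyData.from_table(t, gm_values=gm)
        for z in ("MZ", "DZ"):
            y = data.y[data.zygosity == z]
            emp = np.cov(y.T)
            S = expected_cov(truth, z)
            n = len(y)
            se = np.sqrt((np.outer(np.diag(S), np.diag(S)) + S**2) / n)
            assert np.all(np.abs(emp - S) < 4 * se + 1e-12)

    def test_no_coupling_outside_cluster(self):
        truth = pt.plant_coupling(pt.default_path_model(), "e", 0.6)
        cfg = small_config(
            10, n_mz_pairs=2000, n_dz_pairs=2000, n_singletons=0,
            dropout_rate_occasion2=0.0, smoothing_fwhm_voxels=0.0,
            assay_log_sd=0.0, detection_limit=0.0, cluster_model=truth,
        )
        cohort = simulate_cohort(cfg)
        occ1 = (cohort.table["occasion"] == 1).to_numpy()
        t = cohort.table[occ1]
        h = np.log(t.hormone_day1 / t.creatinine_day1)
        r_in = np.corrcoef(h, cohort.gm_at_voxel((1, 1, 1))[occ1])[0, 1]
        r_out = np.corrcoef(h, cohort.gm_at_voxel((0, 0, 0))[occ1])[0, 1]
        assert r_in > 0.2
        assert abs(r_out) < 0.05

    def test_smoothing_preserves_marginal_variance(self):
        base = simulate_cohort(small_config(11, smoothing_fwhm_voxels=0.0,
                                            grid_shape=(8, 8, 8), signal_cluster=None))
        smooth = simulate_cohort(small_config(11, smoothing_fwhm_voxels=2.0,
                                              grid_shape=(8, 8, 8), signal_cluster=None))
        v0 = base.voxel_data.reshape(len(base.table), -1).var(axis=0).mean()
        v1 = smooth.voxel_data.reshape(len(smooth.table), -1).var(axis=0).mean()
        assert v1 == pytest.approx(v0, rel=0.15)


class TestValidationAndIO:
    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="dropout"):
            small_config(0, dropout_rate_occasion2=1.5).validate()
        with pytest.raises(ValueError, match="outside grid"):
            small_config(0, signal_cluster=[(5, 0, 0)]).validate()
        with pytest.raises(ValueError, match="non-negative"):
            small_config(0, n_mz_pairs=-1).validate()

    def test_invalid_path_model_rejected_before_sampling(self):
        bad = pt.default_path_model()
        bad.R_e = np.full((4, 4), 0.99)
        np.fill_diagonal(bad.R_e, 1.0)
        bad.R_e[0, 1] = bad.R_e[1, 0] = -0.99  # not PSD
        with pytest.raises(ValueError, match="positive semidefinite"):
            simulate_cohort(small_config(0, path_model=bad))

    def test_write_read_round_trip(self, tmp_path):
        cohort = simulate_cohort(small_config(12))
        csv = write_cohort(cohort, str(tmp_path))
        back = read_cohort(csv)
        for col in ("hormone_day1", "creatinine_day2", "age"):
            np.testing.assert_allclose(
                back.table[col].to_numpy(), cohort.table[col].to_numpy(),
                rtol=1e-12, equal_nan=True,
            )
        assert back.table["below_limit_day1"].tolist() == cohort.table["below_limit_day1"].tolist()
        np.testing.assert_allclose(back.voxel_data, cohort.voxel_data, rtol=0, atol=0)
        assert back.grid_shape == cohort.grid_shape
        assert back.hormone == cohort.hormone

    def test_missing_hormone_preserved_as_nan(self, tmp_path):
        cohort = simulate_cohort(small_config(13, detection_limit=0.6))
        back = read_cohort(write_cohort(cohort, str(tmp_path)))
        assert back.table["hormone_day1"].isna().equals(cohort.table["hormone_day1"].isna())

    def test_nifti_header_grid_matches_config(self, tmp_path):
        import nibabel as nib
        import os

        cohort = simulate_cohort(small_config(14))
        csv = write_cohort(cohort, str(tmp_path))
        rel = read_cohort(csv, load_maps=False).table["voxel_map_path"].iloc[0]
        img = nib.load(os.path.join(tmp_path, rel))
        assert tuple(img.shape) == (3, 3, 3)
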