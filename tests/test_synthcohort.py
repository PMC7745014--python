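"""Generator correctness: planted sources, group effects, copula coupling,
volume synthesis and its exactness as a linear mixture."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from sbmgm import (
    SimulationConfig,
    generate_cohort,
    generate_sources,
    load_cohort,
    synthesize_matrix,
    synthesize_volumes,
)
from sbmgm.errors import SimulationError
from sbmgm.sbmstats import compare_groups, standardize_loadings
from sbmgm.synthcohort import baseline_template

from conftest import SMALL_CFG, reseed


class TestGenerateSources:
    def test_pairwise_near_orthogonality(self):
        cfg = SimulationConfig(seed=7, k_true=5)
        sources, mask = generate_sources(cfg)
        assert sources.shape == (5, int(mask.sum()))
        corr = np.corrcoef(sources)
        off = np.abs(corr - np.eye(5))
        assert off.max() < 0.2

    def test_unit_variance_and_nonnegative(self):
        sources, _ = generate_sources(SimulationConfig(seed=3, k_true=4))
        np.testing.assert_allclose(sources.std(axis=1), 1.0, rtol=1e-12)
        assert (sources >= 0).all()

    def test_single_unsmoothed_blob_is_a_gaussian_around_its_peak(self):
        cfg = SimulationConfig(
            seed=11, k_true=2, blobs_per_source=1, smoothing_fwhm_mm=0.0
        )
        sources, mask = generate_sources(cfg)
        coords = np.argwhere(mask).astype(float)
        sigma = cfg.blob_fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / cfg.voxel_size_mm
        for row in sources:
            center = coords[np.argmax(row)]
            d2 = ((coords - center) ** 2).sum(axis=1)
            expected = np.exp(-d2 / (2 * sigma**2))
            # single blob: the map is exactly a Gaussian around its max
            assert np.corrcoef(row, expected)[0, 1] > 0.999999

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=9, k_true=3)
        s1, m1 = generate_sources(cfg)
        s2, m2 = generate_sources(cfg)
        assert np.array_equal(s1, s2) and np.array_equal(m1, m2)

    def test_grid_too_small_raises(self):
        cfg = dataclasses.replace(SMALL_CFG, grid_shape=(4, 4, 4), k_true=8)
        with pytest.raises(SimulationError):
            generate_sources(cfg)


class TestGenerateCohort:
    def test_groups_partition_and_cortisol_positive(self):
        truth = generate_cohort(reseed(SMALL_CFG, 5))
        table = truth.subject_table
        assert (table["group"] == "HS").sum() == SMALL_CFG.n_hs
        assert (table["group"] == "MDD").sum() == SMALL_CFG.n_mdd
        assert (table["cortisol_nmol_l"] > 0).all()
        assert truth.loadings_true.shape == (81, SMALL_CFG.k_true)

    def test_null_effect_rejection_rate_is_nominal(self):
        """With no planted effect the per-component t-test rejects at
        ~alpha; check the empirical rate against binomial error."""
        cfg = dataclasses.replace(SMALL_CFG, effect_d={}, rho_target=0.0)
        groups = None
        hits = 0
        n_seeds = 1000
        for s in range(n_seeds):
            truth = generate_cohort(reseed(cfg, s))
            if groups is None:
                groups = truth.subject_table["group"].to_numpy()
            col = truth.loadings_true[:, 0]
            t, p = stats.ttest_ind(col[groups == "HS"], col[groups == "MDD"])
            hits += p < 0.05
        rate = hits / n_seeds
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_seeds)

    def test_null_coupling_spearman_width(self):
        """rho_target=0: the |Spearman| null width at n=42 matches the
        theoretical tail mass (binomial consistency over 500 seeds)."""
        cfg = dataclasses.replace(SMALL_CFG, effect_d={}, rho_target=0.0)
        n_seeds, inside = 500, 0
        for s in range(n_seeds):
            truth = generate_cohort(reseed(cfg, s))
            mdd = truth.subject_table["group"] == "MDD"
            rho = stats.spearmanr(
                truth.loadings_true[mdd.to_numpy(), cfg.cortisol_component],
                truth.subject_table.loc[mdd, "cortisol_nmol_l"],
            ).statistic
            inside += abs(rho) < 0.30
        # theoretical P(|rho| < 0.30) under the null at n=42 (t-approx)
        n = 42
        t = 0.30 * np.sqrt((n - 2) / (1 - 0.30**2))
        p_th = 1.0 - 2 * stats.t.sf(t, n - 2)
        assert abs(inside / n_seeds - p_th) < 3 * np.sqrt(p_th * (1 - p_th) / n_seeds)

    def test_planted_effect_size_recovered_on_average(self):
        """d = 0.84 planted on one component: mean recovered |d| over 200
        seeds lands within 0.1 of the target."""
        cfg = dataclasses.replace(
            SMALL_CFG, effect_d={0: 0.84}, rho_target=0.0
        )
        ds = []
        for s in range(200):
            truth = generate_cohort(reseed(cfg, s))
            groups = truth.subject_table["group"].to_numpy()
            res = compare_groups(
                standardize_loadings(truth.loadings_true[:, :1]), groups, m=1
            )
            ds.append(res[0].cohens_d)
        assert abs(np.mean(ds) - 0.84) < 0.1

    def test_copula_calibration(self):
        """Expected Spearman of the linked pair matches rho_target within
        0.05 over 1,000 draws."""
        rhos = []
        for s in range(1000):
            truth = generate_cohort(reseed(SMALL_CFG, s))
            mdd = (truth.subject_table["group"] == "MDD").to_numpy()
            rhos.append(
                stats.spearmanr(
                    truth.loadings_true[mdd, SMALL_CFG.cortisol_component],
                    truth.subject_table["cortisol_nmol_l"].to_numpy()[mdd],
                ).statistic
            )
        assert abs(np.mean(rhos) - SMALL_CFG.rho_target) < 0.05

    def test_perfect_coupling_with_noise_is_infeasible(self):
        cfg = dataclasses.replace(SMALL_CFG, rho_target=1.0, noise_sd=0.5)
        with pytest.raises(SimulationError):
            generate_cohort(cfg)

    def test_deterministic(self):
        t1 = generate_cohort(reseed(SMALL_CFG, 4))
        t2 = generate_cohort(reseed(SMALL_CFG, 4))
        assert np.array_equal(t1.loadings_true, t2.loadings_true)
        assert t1.subject_table.equals(t2.subject_table)


class TestSynthesizeVolumes:
    def test_identity_mixture_reproduces_source(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, noise_sd=0.0)
        truth = generate_cohort(cfg)
        truth.loadings_true = np.zeros_like(truth.loadings_true)
        truth.loadings_true[0, 0] = 1.0
        x = synthesize_matrix(truth, cfg)
        residual = x[0] - baseline_template(truth, cfg)
        np.testing.assert_allclose(residual, truth.sources_true[0], atol=1e-10)

    def test_residual_sd_matches_noise_level(self, default_cohort):
        cfg, truth, x = default_cohort
        clean = truth.loadings_true @ truth.sources_true + baseline_template(
            truth, cfg
        )
        resid = x - clean
        unclipped = (x > 0).all(axis=0)
        assert unclipped.mean() > 0.99  # clipping is rare by construction
        voxel_sd = resid[:, unclipped].std(axis=0)
        assert abs(voxel_sd.mean() - cfg.noise_sd) < 0.2 * cfg.noise_sd

    def test_written_volumes_roundtrip_bitwise(self, tmp_path, small_cfg):
        truth = generate_cohort(small_cfg)
        volumes, table = synthesize_volumes(truth, small_cfg, out_dir=tmp_path)
        loaded = load_cohort(tmp_path, table)
        for orig, back in zip(volumes, loaded):
            assert np.array_equal(orig.data, back.data)

    def test_shape_mismatch_raises(self, small_cfg):
        truth = generate_cohort(small_cfg)
        truth.loadings_true = truth.loadings_true[:, :-1]
        with pytest.raises(SimulationError):
            synthesize_matrix(truth, small_cfg)

    def test_deterministic_matrix(self, small_cfg):
        truth = generate_cohort(small_cfg)
        x1 = synthesize_matrix(truth, small_cfg)
        x2 = synthesize_matrix(truth, small_cfg)
        assert np.array_equal(x1, x2)
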