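import numpy as np
import pandas as pd
import pytest
from scipy import stats

from indexbias import simulate as sim


def small_scenario(**kw):
    base = dict(m_total=400, m_inc_only=40, m_prog_only=40, m_both=40,
                n_individuals=1500, seed=0)
    base.update(kw)
    return sim.SimulationScenario(**base)


class TestScenarioValidation:
    def test_counts_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            sim.SimulationScenario(m_total=100, m_inc_only=60, m_prog_only=60, m_both=0)

    def test_shares_exceeding_unity_rejected(self):
        with pytest.raises(ValueError):
            sim.SimulationScenario(h2_x=0.7, conf_share_x=0.5)

    def test_bad_maf_range_rejected(self):
        with pytest.raises(ValueError):
            sim.SimulationScenario(maf_low=0.4, maf_high=0.2)

    def test_round_trips_through_dict(self):
        sc = small_scenario(rho_shared=0.5)
        assert sim.SimulationScenario.from_dict(sc.to_dict()) == sc


class TestSimulateGenotypes:
    def test_hwe_moments(self):
        rng = np.random.default_rng(0)
        maf = np.full(30, 0.5)
        dos, _ = sim.simulate_genotypes(20_000, 30, 0.01, 0.49, rng, maf=maf)
        assert dos.mean() == pytest.approx(1.0, abs=0.02)

    def test_column_variance_is_binomial(self):
        rng = np.random.default_rng(1)
        dos, maf = sim.simulate_genotypes(50_000, 20, 0.05, 0.45, rng)
        expected = 2 * maf * (1 - maf)
        assert np.allclose(dos.var(axis=0), expected, rtol=0.08)

    def test_seed_reproducibility(self):
        d1, m1 = sim.simulate_genotypes(100, 10, 0.01, 0.49, np.random.default_rng(7))
        d2, m2 = sim.simulate_genotypes(100, 10, 0.01, 0.49, np.random.default_rng(7))
        assert np.array_equal(d1, d2) and np.array_equal(m1, m2)


class TestDrawEffects:
    def test_heritability_hit_exactly(self):
        sc = small_scenario(h2_x=0.4, h2_y=0.3)
        rng = np.random.default_rng(2)
        maf = rng.uniform(sc.maf_low, sc.maf_high, sc.m_total)
        truth = sim.draw_effect_vectors(sc, maf, rng)
        assert np.sum(truth.beta_gx_true**2 * truth.vg) == pytest.approx(0.4)
        assert np.sum(truth.beta_gy_true**2 * truth.vg) == pytest.approx(0.3)

    def test_zero_heritability_zero_effects(self):
        sc = small_scenario(h2_x=0.0)
        rng = np.random.default_rng(3)
        maf = rng.uniform(0.01, 0.49, sc.m_total)
        truth = sim.draw_effect_vectors(sc, maf, rng)
        assert np.all(truth.beta_gx_true == 0)

    def test_genetic_correlation_scales_with_shared_fraction(self):
        # corr 0.5 at shared SNPs with half the causal SNPs shared
        # -> genome-wide genetic correlation ~ 0.25
        sc = sim.SimulationScenario(m_total=40_000, m_inc_only=2000,
                                    m_prog_only=2000, m_both=2000, rho_shared=0.5)
        rng = np.random.default_rng(4)
        maf = rng.uniform(0.01, 0.49, sc.m_total)
        truth = sim.draw_effect_vectors(sc, maf, rng)
        gencorr = truth.genetic_cov / np.sqrt(sc.h2_x * sc.h2_y)
        assert gencorr == pytest.approx(0.25, abs=0.04)

    def test_category_labels_partition(self):
        sc = small_scenario()
        rng = np.random.default_rng(5)
        maf = rng.uniform(0.01, 0.49, sc.m_total)
        truth = sim.draw_effect_vectors(sc, maf, rng)
        counts = pd.Series(truth.category).value_counts()
        assert counts["inc_only"] == 40 and counts["both"] == 40
        assert counts["null"] == 400 - 120
        assert np.all(truth.beta_gy_true[truth.category == "inc_only"] == 0)


class TestSimulateTraits:
    def test_unit_variance_and_confounder_share(self):
        sc = sim.SimulationScenario(m_total=1000, m_inc_only=100, m_prog_only=100,
                                    m_both=100, n_individuals=40_000)
        rng = np.random.default_rng(6)
        dos, maf = sim.simulate_genotypes(sc.n_individuals, sc.m_total,
                                          sc.maf_low, sc.maf_high, rng)
        truth = sim.draw_effect_vectors(sc, maf, rng)
        x, y, u = sim.simulate_traits(dos, truth, sc, rng)
        assert x.var() == pytest.approx(1.0, abs=0.03)
        assert y.var() == pytest.approx(1.0, abs=0.03)
        # cov(X, U) = sqrt(conf_share) under the structural model
        assert np.cov(x, u)[0, 1] == pytest.approx(np.sqrt(0.4), abs=0.03)

    def test_null_model_gives_independent_standard_normals(self):
        sc = small_scenario(h2_x=0.0, h2_y=0.0, conf_share_x=0.0, conf_share_y=0.0,
                            n_individuals=20_000)
        rng = np.random.default_rng(7)
        dos, maf = sim.simulate_genotypes(sc.n_individuals, sc.m_total, 0.01, 0.49, rng)
        truth = sim.draw_effect_vectors(sc, maf, rng)
        x, y, _ = sim.simulate_traits(dos, truth, sc, rng)
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.02
        assert x.var() == pytest.approx(1.0, abs=0.03)


class TestDichotomize:
    def test_case_fraction_and_prognosis_split(self):
        sc = small_scenario(case_fraction=0.2, n_cases=200, n_controls=300)
        rng = np.random.default_rng(8)
        x = rng.standard_normal(5000)
        y = rng.standard_normal(5000)
        cases, controls, poor = sim.dichotomize_and_sample(x, y, sc, rng)
        assert len(cases) == 200 and len(controls) == 300
        thresh = np.quantile(x, 0.8)
        assert np.all(x[cases] > thresh) and np.all(x[controls] <= thresh)
        assert abs(poor.sum() - 100) <= 1  # median split up to ties

    def test_insufficient_pool_raises(self):
        sc = small_scenario(case_fraction=0.2, n_cases=500, n_controls=100)
        rng = np.random.default_rng(9)
        with pytest.raises(sim.SimulationError):
            sim.dichotomize_and_sample(rng.standard_normal(1000),
                                       rng.standard_normal(1000), sc, rng)

    def test_seeded_sampling_reproducible(self):
        sc = small_scenario(case_fraction=0.3, n_cases=100, n_controls=100)
        x = np.random.default_rng(10).standard_normal(2000)
        y = np.random.default_rng(11).standard_normal(2000)
        c1, k1, p1 = sim.dichotomize_and_sample(x, y, sc, np.random.default_rng(12))
        c2, k2, p2 = sim.dichotomize_and_sample(x, y, sc, np.random.default_rng(12))
        assert np.array_equal(c1, c2) and np.array_equal(k1, k2)


class TestPerSnpScans:
    def test_linear_outcome_equals_dosage(self):
        rng = np.random.default_rng(13)
        dos = rng.binomial(2, 0.3, size=(200, 5)).astype(np.uint8)
        beta, se = sim.per_snp_linear_gwas(dos, dos[:, 2].astype(float))
        assert beta[2] == pytest.approx(1.0)
        assert se[2] == pytest.approx(0.0, abs=1e-8)

    def test_matches_hand_ols_on_toy_data(self):
        g = np.array([[0], [1], [2], [0], [1], [2]], dtype=np.uint8)
        y = np.array([1.0, 2.0, 2.5, 0.5, 2.2, 3.1])
        X = np.column_stack([np.ones(6), g[:, 0]])
        bhat = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ bhat
        s2 = resid @ resid / 4
        se_ref = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        beta, se = sim.per_snp_linear_gwas(g, y)
        assert beta[0] == pytest.approx(bhat[1], rel=1e-12)
        assert se[0] == pytest.approx(se_ref, rel=1e-12)

    def test_linear_null_calibration(self):
        rng = np.random.default_rng(14)
        dos = rng.binomial(2, rng.uniform(0.05, 0.45, 2000)[None, :],
                           size=(500, 2000)).astype(np.uint8)
        y = rng.standard_normal(500)
        beta, se = sim.per_snp_linear_gwas(dos, y)
        t = beta / se
        p = 2 * stats.t.sf(np.abs(t), df=498)
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.02)

    def test_zero_variance_snp_flagged(self):
        dos = np.zeros((50, 2), dtype=np.uint8)
        dos[:, 1] = np.random.default_rng(15).integers(0, 3, 50)
        beta, se = sim.per_snp_linear_gwas(dos, np.random.default_rng(16).normal(size=50))
        assert np.isnan(beta[0]) and np.isfinite(beta[1])

    def test_logistic_matches_collapsed_table_odds_ratio(self):
        # binary dosage -> logistic slope equals the 2x2 table log odds ratio
        g = np.repeat([0, 0, 1, 1], [40, 60, 30, 10]).astype(np.uint8)[:, None]
        y = np.repeat([1, 0, 1, 0], [40, 60, 30, 10]).astype(float)
        beta, se = sim.per_snp_logistic_gwas(g, y)
        log_or = np.log((30 * 60) / (10 * 40))
        assert beta[0] == pytest.approx(log_or, rel=1e-6)
        assert se[0] == pytest.approx(np.sqrt(1/30 + 1/10 + 1/40 + 1/60), rel=1e-6)

    def test_logistic_label_flip_negates_beta(self):
        rng = np.random.default_rng(17)
        g = rng.binomial(2, 0.3, size=(400, 3)).astype(np.uint8)
        y = (rng.random(400) < 0.5).astype(float)
        b1, _ = sim.per_snp_logistic_gwas(g, y)
        b2, _ = sim.per_snp_logistic_gwas(g, 1 - y)
        assert np.allclose(b1, -b2, atol=1e-8)

    def test_logistic_null_calibration(self):
        rng = np.random.default_rng(18)
        dos = rng.binomial(2, rng.uniform(0.1, 0.4, 1500)[None, :],
                           size=(600, 1500)).astype(np.uint8)
        y = (rng.random(600) < 0.5).astype(float)
        beta, se = sim.per_snp_logistic_gwas(dos, y)
        ok = np.isfinite(beta)
        p = 2 * stats.norm.sf(np.abs(beta[ok] / se[ok]))
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.02)

    def test_cox_two_group_hazard_ratio(self):
        rng = np.random.default_rng(19)
        g = rng.integers(0, 2, 4000).astype(np.uint8)[:, None]
        times = rng.exponential(scale=np.where(g[:, 0] == 1, 0.5, 1.0))
        beta, se = sim.per_snp_survival_gwas(g, times)
        assert beta[0] == pytest.approx(np.log(2), abs=3.5 * se[0])

    def test_cox_invariant_to_time_scaling(self):
        rng = np.random.default_rng(20)
        g = rng.binomial(2, 0.3, size=(300, 2)).astype(np.uint8)
        times = rng.exponential(1.0, 300)
        b1, _ = sim.per_snp_survival_gwas(g, times)
        b2, _ = sim.per_snp_survival_gwas(g, 1000.0 * times)
        assert np.allclose(b1, b2, atol=1e-6)

    def test_constant_prognosis_gives_null_cox(self):
        rng = np.random.default_rng(21)
        g = rng.binomial(2, 0.3, size=(500, 4)).astype(np.uint8)
        times = sim.simulate_survival_times(np.zeros(500), rng)
        beta, se = sim.per_snp_survival_gwas(g, times)
        assert np.all(np.abs(beta / se) < 3.5)


class TestSummaryEngine:
    def test_matches_individual_engine_moments(self):
        # the asymptotic sampling distributions must agree with the
        # individual-level per-SNP estimates in mean and spread
        sc = sim.SimulationScenario(m_total=2000, m_inc_only=200, m_prog_only=200,
                                    m_both=200, n_individuals=2000)
        master = np.random.default_rng(22)
        maf = master.uniform(0.01, 0.49, sc.m_total)
        truth = sim.draw_effect_vectors(sc, maf, master)
        bxs, bys = [], []
        for _ in range(3):
            bx_i, sx_i, by_i, sy_i = sim.individual_level_replicate(
                sc, truth, np.random.default_rng(master.integers(2**31)))
            bxs.append(bx_i)
            bys.append(by_i)
        bx_s, sx_s, by_s, sy_s = sim.summary_level_replicate(
            sc, truth, np.random.default_rng(23))
        # mean of prognosis estimates reflects the collider bias slope
        bprime = truth.beta_gy_true + truth.collider_slope * truth.beta_gx_true
        resid_ind = np.mean(bys, axis=0) - bprime
        assert np.mean(resid_ind * truth.beta_gx_true) * sc.m_total / \
            np.sum(truth.beta_gx_true**2) == pytest.approx(0.0, abs=0.15)
        # spreads agree within 5%
        z_ind = (bxs[0] - truth.beta_gx_true) / sx_i
        assert z_ind.std() == pytest.approx(1.0, abs=0.05)
        z_sum = (bx_s - truth.beta_gx_true) / sx_s
        assert z_sum.std() == pytest.approx(1.0, abs=0.05)

    def test_binary_mode_unsupported(self):
        sc = small_scenario(trait_mode="binary_liability")
        rng = np.random.default_rng(24)
        maf = rng.uniform(0.01, 0.49, sc.m_total)
        truth = sim.draw_effect_vectors(sc, maf, rng)
        with pytest.raises(NotImplementedError):
            sim.summary_level_replicate(sc, truth, rng)


class TestRunScenario:
    def test_requires_seed(self):
        with pytest.raises(ValueError):
            sim.run_scenario(small_scenario(), n_reps=2, seed=None)

    def test_null_everything_nominal(self):
        sc = sim.SimulationScenario(m_total=20_000, m_inc_only=0, m_prog_only=0,
                                    m_both=0, conf_share_x=0.0, conf_share_y=0.0,
                                    h2_x=0.0, h2_y=0.0)
        with pytest.raises(Exception):
            # no incidence signal at all: the slope regression must refuse
            # (dilution correction infeasible) rather than return nonsense
            sim.run_scenario(sc, n_reps=2, engine="summary", seed=1)

    def test_no_incidence_effects_adjusted_equals_unadjusted(self):
        sc = sim.SimulationScenario(m_total=20_000, m_inc_only=0, m_prog_only=1000,
                                    m_both=1000, rho_shared=0.0)
        tab = sim.run_scenario(sc, n_reps=5, engine="summary", seed=2,
                               slope_method="raw")
        u = tab.loc["type1_all_null", "unadjusted"]
        a = tab.loc["type1_all_null", "adjusted"]
        assert a == pytest.approx(u, abs=0.35)

    def test_deterministic_under_seed(self):
        sc = sim.SimulationScenario(m_total=5000, m_inc_only=250, m_prog_only=250,
                                    m_both=250)
        t1 = sim.run_scenario(sc, n_reps=3, engine="summary", seed=9)
        t2 = sim.run_scenario(sc, n_reps=3, engine="summary", seed=9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_metrics_table_shape(self):
        sc = sim.SimulationScenario(m_total=5000, m_inc_only=250, m_prog_only=250,
                                    m_both=250)
        tab = sim.run_scenario(sc, n_reps=2, engine="summary", seed=3)
        assert list(tab.index) == sim.METRIC_ROWS
        assert list(tab.columns) == ["unadjusted", "adjusted",
                                     "mc_se_unadjusted", "mc_se_adjusted"]
        assert tab.attrs["b_true"] < 0
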