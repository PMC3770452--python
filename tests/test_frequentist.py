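"""Unit and property tests for the frequentist test battery.

Oracles: scipy's 2x2 Pearson chi-square for the doubled-sample allelic
test, the individual-level N*r^2 identity for the Cochran-Armitage
trend statistic, exhaustive enumeration of the bootstrap null for tiny
tables, and grid searches over the allelic null manifold for the
constrained MLE.
"""

import itertools

import numpy as np
import pytest
from scipy import stats

from homtest import (
    GenotypeTable,
    armitage_trend,
    asymptotic_pvalue,
    corrected_allelic_chisq,
    fit_constrained_allelic,
    fit_pooled_genotypic,
    genotypic_chisq,
    hwe_chisq,
    usual_allelic_chisq,
)
from homtest.frequentist import (
    _corrected_stats_batch,
    _wlog,
    chisq_statistic,
    fit_allelic_batch,
    mc_exact_pvalue,
)

from conftest import random_tables


class TestPooledFit:
    def test_real_data_closed_form(self, table1):
        fit = fit_pooled_genotypic(table1)
        np.testing.assert_allclose(fit.estimate.gamma_arr, np.array([79, 125, 89]) / 293)
        assert fit.expected_case.sum() == pytest.approx(188, abs=1e-9)
        assert fit.expected_control.sum() == pytest.approx(105, abs=1e-9)

    def test_identical_rows(self):
        fit = fit_pooled_genotypic(GenotypeTable(3, 4, 5, 3, 4, 5))
        np.testing.assert_allclose(fit.estimate.gamma_arr, np.array([3, 4, 5]) / 12)

    def test_boundary_estimate_allowed(self):
        fit = fit_pooled_genotypic(GenotypeTable(1, 0, 0, 0, 0, 1))
        np.testing.assert_allclose(fit.estimate.gamma_arr, [0.5, 0.0, 0.5])
        assert fit.boundary


class TestGenotypicChisq:
    def test_real_data(self, table1):
        r = genotypic_chisq(table1)
        assert r.df == 2
        assert round(r.p_value, 3) == 0.152

    def test_perfect_homogeneity(self, identical_rows):
        r = genotypic_chisq(identical_rows)
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_mc_matches_asymptotic_roughly(self, table1):
        r = genotypic_chisq(table1, method="monte_carlo", n_reps=20_000, seed=7)
        assert r.mc_ci[0] <= r.p_value <= r.mc_ci[1]
        assert abs(r.p_value - 0.152) < 0.02


class TestUsualAllelic:
    def test_real_data(self, table1):
        r = usual_allelic_chisq(table1)
        assert round(r.p_value, 3) == 0.049
        assert "Hardy-Weinberg" in r.warning

    def test_equal_allele_proportions(self):
        # different genotype rows, identical allele frequencies
        t = GenotypeTable(2, 0, 2, 0, 4, 0)
        r = usual_allelic_chisq(t)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_2x2_pearson(self, seed):
        for t in random_tables(seed, 5):
            obs = np.array(
                [
                    [2 * t.x_AA + t.x_AB, 2 * t.x_BB + t.x_AB],
                    [2 * t.y_AA + t.y_AB, 2 * t.y_BB + t.y_AB],
                ]
            )
            if np.any(obs.sum(axis=0) == 0):
                continue
            expected = stats.chi2_contingency(obs, correction=False)
            r = usual_allelic_chisq(t)
            assert r.statistic == pytest.approx(expected.statistic, abs=1e-10)
            assert r.p_value == pytest.approx(expected.pvalue, abs=1e-10)


class TestConstrainedAllelicFit:
    def test_null_satisfied_exactly(self):
        # sample allele frequencies already agree -> unconstrained MLE feasible
        t = GenotypeTable(10, 20, 10, 5, 10, 5)
        fit = fit_constrained_allelic(t)
        np.testing.assert_allclose(fit.estimate.gamma_arr, [0.25, 0.5, 0.25], atol=1e-9)
        np.testing.assert_allclose(fit.estimate.pi_arr, [0.25, 0.5, 0.25], atol=1e-9)
        r = corrected_allelic_chisq(t)
        assert r.statistic == pytest.approx(0.0, abs=1e-9)
        assert r.p_value == pytest.approx(1.0, abs=1e-6)

    def test_constraint_residual(self, table1):
        fit = fit_constrained_allelic(table1)
        est = fit.estimate
        assert abs(est.allele_freq_case - est.allele_freq_control) < 1e-8
        assert fit.expected_case.sum() == pytest.approx(table1.n, abs=1e-9)
        assert fit.expected_control.sum() == pytest.approx(table1.m, abs=1e-9)

    def test_beats_moderate_grid(self, table1):
        # coarse grid over the null manifold in (gamma_AB, pi_AA, pi_AB)
        fit = fit_constrained_allelic(table1)
        x, y = table1.case, table1.control
        step = 0.02
        vals = np.arange(0.0, 1.0 + step / 2, step)
        paa, pab, gab = np.meshgrid(vals, vals, vals, indexing="ij")
        lam = paa + pab / 2
        gaa = lam - gab / 2
        gbb = 1 - gaa - gab
        pbb = 1 - paa - pab
        ok = (gaa >= 0) & (gbb >= 0) & (pbb >= 0) & (lam <= 1)
        G = np.stack([gaa[ok], gab[ok], gbb[ok]], axis=-1)
        P = np.stack([paa[ok], pab[ok], pbb[ok]], axis=-1)
        grid_best = (_wlog(x, G) + _wlog(y, P)).max()
        assert fit.log_likelihood >= grid_best - 1e-9

    def test_constrained_ll_never_beats_unconstrained(self):
        for t in random_tables(11, 20):
            fit = fit_constrained_allelic(t)
            gu = t.case / t.n
            pu = t.control / t.m
            unconstrained = _wlog(t.case, gu) + _wlog(t.control, pu)
            assert fit.log_likelihood <= unconstrained + 1e-9

    def test_batch_matches_scipy_optimizer(self):
        # independent oracle: scipy SLSQP maximisation in the profile coords
        from scipy.optimize import minimize_scalar

        from homtest.frequentist import _inner_freqs

        for t in random_tables(3, 10):
            fit = fit_constrained_allelic(t)
            x, y = t.case.astype(float), t.control.astype(float)

            def neg_profile(lam):
                g = _inner_freqs(np.array(lam), x)
                p = _inner_freqs(np.array(lam), y)
                return -float(_wlog(x, g) + _wlog(y, p))

            r = minimize_scalar(neg_profile, bounds=(1e-9, 1 - 1e-9), method="bounded",
                                options={"xatol": 1e-12})
            assert fit.log_likelihood >= -r.fun - 1e-7


class TestCorrectedAllelic:
    def test_real_data_asymptotic_close_to_trend(self, table1):
        r = corrected_allelic_chisq(table1)
        trend = armitage_trend(table1)
        assert r.df == 1
        # asymptotically equivalent tests; on n=293 they sit within ~0.01
        assert abs(r.p_value - trend.p_value) < 0.01

    def test_mc_real_data_small(self, table1):
        r = corrected_allelic_chisq(table1, method="monte_carlo", n_reps=5_000, seed=3)
        assert r.mc_ci[0] <= r.p_value <= r.mc_ci[1]
        assert abs(r.p_value - 0.069) < 0.02

    def test_statistic_nonnegative_random(self):
        for t in random_tables(21, 15):
            assert corrected_allelic_chisq(t).statistic >= 0.0


class TestArmitageTrend:
    def test_real_data(self, table1):
        assert round(armitage_trend(table1).p_value, 3) == 0.066

    def test_identical_rows(self, identical_rows):
        r = armitage_trend(identical_rows)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == 1.0

    def test_degenerate_single_column(self):
        with pytest.raises(ValueError, match="undefined"):
            armitage_trend(GenotypeTable(0, 5, 0, 0, 3, 0))

    def test_matches_individual_level_identity(self):
        # CA trend statistic == N * pearson_r^2 on expanded individual data
        for t in random_tables(5, 8):
            col = t.case + t.control
            if np.count_nonzero(col) < 2:
                continue
            disease = np.concatenate([np.ones(t.n), np.zeros(t.m)])
            score = np.concatenate(
                [np.repeat([0, 1, 2], t.case), np.repeat([0, 1, 2], t.control)]
            )
            if np.std(score) == 0:
                continue
            r = stats.pearsonr(disease, score).statistic
            expected = len(disease) * r * r
            assert armitage_trend(t).statistic == pytest.approx(expected, rel=1e-10)

    def test_score_orientation_invariant(self, table1):
        a = armitage_trend(table1, scores=(0, 1, 2))
        b = armitage_trend(table1, scores=(2, 1, 0))
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)


class TestHWEChisq:
    def test_real_data_groups(self, table1):
        assert round(hwe_chisq(table1.case).p_value, 3) == 0.111
        assert round(hwe_chisq(table1.control).p_value, 3) == 0.060

    def test_exact_hwe(self):
        r = hwe_chisq([25, 50, 25])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == 1.0

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            hwe_chisq([10, 0, 0])


class TestAsymptoticPvalue:
    @pytest.mark.parametrize("stat", [0.0, 0])
    def test_zero_statistic(self, stat):
        assert asymptotic_pvalue(stat, 1) == 1.0
        assert asymptotic_pvalue(stat, 2) == 1.0

    def test_quantile_identities(self):
        assert asymptotic_pvalue(3.841458820694124, 1) == pytest.approx(0.05, abs=1e-9)
        assert asymptotic_pvalue(5.991464547107979, 2) == pytest.approx(0.05, abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            asymptotic_pvalue(-1.0, 1)


class TestMonteCarloEngine:
    def test_zero_observed_gives_one(self, identical_rows):
        r = genotypic_chisq(identical_rows, method="monte_carlo", n_reps=500, seed=1)
        assert r.p_value == 1.0

    def test_determinism(self, table1):
        a = corrected_allelic_chisq(table1, method="monte_carlo", n_reps=2_000, seed=42)
        b = corrected_allelic_chisq(table1, method="monte_carlo", n_reps=2_000, seed=42)
        assert a.p_value == b.p_value
        assert a.mc_ci == b.mc_ci

    def test_ci_width_scales_as_sqrt_reps(self, table1):
        r1 = corrected_allelic_chisq(table1, method="monte_carlo", n_reps=2_000, seed=9)
        r2 = corrected_allelic_chisq(table1, method="monte_carlo", n_reps=8_000, seed=9)
        w1 = r1.mc_ci[1] - r1.mc_ci[0]
        w2 = r2.mc_ci[1] - r2.mc_ci[0]
        assert w2 == pytest.approx(w1 / 2, rel=0.25)

    def test_tiny_table_enumeration(self):
        # exhaustive product-multinomial enumeration of the bootstrap null
        t = GenotypeTable(2, 1, 0, 0, 1, 2)
        fit = fit_pooled_genotypic(t)
        n, m = t.n, t.m
        comps = [c for c in itertools.product(range(4), repeat=3) if sum(c) == 3]

        def stat(xr, yr):
            pooled = (xr + yr) / (n + m)
            return chisq_statistic(xr, n * pooled) + chisq_statistic(yr, m * pooled)

        obs = float(stat(t.case[None], t.control[None])[0])
        theta = fit.estimate.gamma_arr
        p_exact = 0.0
        for cx in comps:
            px = stats.multinomial.pmf(cx, 3, theta)
            for cy in comps:
                py = stats.multinomial.pmf(cy, 3, theta)
                s = float(stat(np.array(cx)[None].astype(float), np.array(cy)[None].astype(float))[0])
                if s >= obs - 1e-9:
                    p_exact += px * py
        phat, ci = mc_exact_pvalue(obs, stat, theta, theta, n, m, n_reps=20_000, seed=17)
        se = np.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert abs(phat - p_exact) <= 3 * se + 1e-12


class TestChisqConventions:
    def test_expected_zero_observed_zero(self):
        assert chisq_statistic(np.array([0.0, 1.0]), np.array([0.0, 1.0])) == 0.0

    def test_expected_zero_observed_positive(self):
        assert np.isinf(chisq_statistic(np.array([1.0, 0.0]), np.array([0.0, 1.0])))
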