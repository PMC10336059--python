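"""Mixed-model inference: recovery, DIC behavior, and summary statistics."""

import numpy as np
import pandas as pd
import pytest

from ethotype import (
    BayesianLMM,
    BivariateBayesianLMM,
    TraitSimConfig,
    adjusted_repeatability,
    backward_reduce,
    pmcmc,
    repeatability_significance,
    simulate_trait_data,
    simulate_trait_pair,
    syndrome_estimate,
    syndrome_from_draws,
    variance_f_test,
)
from ethotype.gibbs import deviance_univariate

FAST = dict(n_iter=3000, burn_in=600, thin=3, check_convergence=False)
FAST_BIV = dict(n_iter=10000, burn_in=2000, thin=8)


def _sim(seed, v_ind=0.4, v_e=0.6, n=70, k=4, beta=(1.0, 0.03, 0.2, 0.0)):
    return simulate_trait_data(TraitSimConfig(
        n_individuals=n, n_trials=k, v_ind=v_ind, v_e=v_e, beta=beta,
        seed=seed))


class TestUnivariateGibbs:
    def test_fixed_seed_gives_bit_identical_chains(self):
        df = _sim(1)
        a = BayesianLMM(random_state=3, **FAST).fit(df)
        b = BayesianLMM(random_state=3, **FAST).fit(df)
        assert np.array_equal(a.v_ind_draws_, b.v_ind_draws_)
        assert np.array_equal(a.beta_draws_.to_numpy(), b.beta_draws_.to_numpy())
        assert np.array_equal(a.deviance_draws_, b.deviance_draws_)

    def test_posterior_recovers_variances_and_slope(self):
        covered, vi_means = 0, []
        n_rep = 12
        for s in range(n_rep):
            df = _sim(400 + s)
            m = BayesianLMM(random_state=s, **FAST).fit(df)
            lo, hi = np.quantile(m.beta_draws_["trial"], [0.025, 0.975])
            covered += lo <= 0.03 <= hi
            vi_means.append(m.v_ind_draws_.mean())
        assert covered >= int(0.75 * n_rep)
        assert 0.25 <= np.mean(vi_means) <= 0.55

    def test_posterior_means_match_anova_moment_estimates(self):
        df = _sim(7, n=200, beta=(0.0, 0.0, 0.0, 0.0))
        m = BayesianLMM(fixed_terms=(), random_state=0, **FAST).fit(df)
        k = 4
        g = df.groupby("id")["value"]
        msb = g.mean().var(ddof=1) * k
        msw = g.var(ddof=1).mean()
        v_ind_hat = (msb - msw) / k
        assert m.v_ind_draws_.mean() == pytest.approx(v_ind_hat, rel=0.10)
        assert m.v_e_draws_.mean() == pytest.approx(msw, rel=0.10)

    def test_chain_invariance_under_double_thinning(self):
        df = _sim(11)
        a = BayesianLMM(n_iter=4000, burn_in=1000, thin=3,
                        check_convergence=False, random_state=1).fit(df)
        b = BayesianLMM(n_iter=8000, burn_in=1000, thin=6,
                        check_convergence=False, random_state=2).fit(df)
        assert a.v_ind_draws_.mean() == pytest.approx(b.v_ind_draws_.mean(),
                                                      abs=0.05)

    def test_every_variance_draw_positive(self):
        m = BayesianLMM(random_state=0, **FAST).fit(_sim(2))
        assert np.all(m.v_ind_draws_ > 0)
        assert np.all(m.v_e_draws_ > 0)

    def test_singular_design_names_collinear_column(self):
        df = _sim(3)
        df["sample"] = "wild"  # indicator column becomes all zero
        with pytest.raises(ValueError, match="sample"):
            BayesianLMM(random_state=0, **FAST).fit(df)

    def test_zero_variance_response_rejected(self):
        df = _sim(3)
        df["value"] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            BayesianLMM(random_state=0, **FAST).fit(df)


class TestRepeatability:
    def test_plugin_ratio_on_degenerate_draws(self):
        est = adjusted_repeatability([0.66], [0.95])
        assert round(est.r_mean, 2) == 0.41
        est = adjusted_repeatability([560745.5], [1697069.0])
        assert round(est.r_mean, 2) == 0.25

    def test_zero_between_individual_variance_gives_zero_r(self):
        est = adjusted_repeatability(np.zeros(10), np.ones(10))
        assert est.r_mean == 0.0

    def test_r_draws_bounded_in_unit_interval(self):
        m = BayesianLMM(random_state=5, **FAST).fit(_sim(5))
        est = m.repeatability()
        assert np.all((est.r_draws >= 0) & (est.r_draws <= 1))
        assert est.bci[0] <= est.r_mean <= est.bci[1]

    def test_signal_detected_by_dic_rule(self):
        # R_true = 0.5 with 70 individuals: random effect must be supported
        df = _sim(21, v_ind=0.5, v_e=0.5)
        est = repeatability_significance(df, random_state=0, **FAST)
        assert est.delta_dic > 2
        assert est.significant
        assert est.dic_constrained == pytest.approx(est.dic + est.delta_dic)

    def test_null_not_flagged_significant(self):
        hits = 0
        for s in range(5):
            df = _sim(600 + s, v_ind=0.0, v_e=1.0)
            est = repeatability_significance(df, random_state=s, **FAST)
            hits += est.significant
        assert hits <= 1


class TestPmcmc:
    def test_hand_counted_cases(self):
        assert pmcmc([-1.0, 1.0, 1.0, 1.0]) == 0.5
        assert pmcmc(np.ones(200)) == pytest.approx(1 / 200)
        rng = np.random.default_rng(0)
        sym = rng.normal(size=100_000)
        assert pmcmc(sym) == pytest.approx(1.0, abs=0.02)


class TestDic:
    def test_deviance_closed_form_on_two_points(self):
        y = np.array([1.0, 3.0])
        X = np.ones((2, 1))
        beta = np.array([2.0])
        s2 = 4.0
        expected = -2 * np.sum(
            -0.5 * np.log(2 * np.pi * s2) - (y - 2.0) ** 2 / (2 * s2))
        got = deviance_univariate(y, X, np.array([0, 1]), beta, None, s2)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_effective_parameters_near_truth_on_clean_linear_data(self):
        rng = np.random.default_rng(4)
        n = 400
        df = pd.DataFrame({
            "id": np.repeat([f"i{j}" for j in range(100)], 4),
            "trial": np.tile([1, 2, 3, 4], 100),
            "sample": "wild", "length_cm": 12.0,
        })
        df["value"] = 0.5 * df["trial"] + rng.normal(0, 1.0, n)
        m = BayesianLMM(fixed_terms=("trial",), include_random=False,
                        random_state=0, **FAST).fit(df)
        # intercept + slope + variance: pD should be near 3
        assert m.pd_ == pytest.approx(3.0, abs=1.5)

    def test_random_effect_lowers_dic_when_truth_has_one(self):
        for s in range(3):
            df = _sim(900 + s, v_ind=1.5, v_e=0.5)
            est = repeatability_significance(df, random_state=s, **FAST)
            assert est.delta_dic > 2

    def test_dic_accessor_matches_fitted_attribute(self):
        from ethotype import dic
        m = BayesianLMM(random_state=0, **FAST).fit(_sim(1))
        assert dic(m) == m.dic_ == m.dbar_ + m.pd_


class TestBackwardReduction:
    def test_strong_sample_effect_retained_null_length_droppable(self):
        kept_sample, dropped_length = 0, 0
        for s in range(3):
            df = _sim(50 + s, beta=(1.0, 0.0, 1.5, 0.0))
            kept, hist = backward_reduce(df, random_state=s, **FAST)
            kept_sample += "sample" in kept
            dropped_length += "length" not in kept
        assert kept_sample == 3
        assert dropped_length >= 2

    def test_no_removable_terms_returns_input(self):
        df = _sim(1)
        kept, hist = backward_reduce(df, fixed_terms=(), random_state=0, **FAST)
        assert kept == ()
        assert len(hist) == 1


def _pair(seed, r_ind=0.6, r_e=0.2, n=70):
    return simulate_trait_pair(TraitSimConfig(
        n_individuals=n, n_trials=4, v_ind=0.4, v_e=0.6,
        trait_pair_corr=(r_ind, r_e), trait_names=("a", "b"), seed=seed))


class TestBivariate:
    def test_duplicated_trait_pushes_correlations_to_one(self):
        df = _sim(13)
        dup = pd.concat([df.assign(trait="a"), df.assign(trait="b")],
                        ignore_index=True)
        m = BivariateBayesianLMM(responses=("a", "b"), random_state=0,
                                 **FAST_BIV).fit(dup)
        c = m.correlations()
        # the identity prior scale shrinks r_ind slightly at q = 70
        assert c.r_ind > 0.9
        assert c.r_e > 0.98

    @pytest.mark.parametrize("seed", [30, 31])
    def test_posterior_matches_moment_estimators_of_g_and_r(self, seed):
        # single-realization check: the posterior must track the data's own
        # moment (between-/within-individual covariance) estimates
        df = _pair(seed)
        w = df.pivot_table(index=["id", "trial"], columns="trait",
                           values="value")
        dev = w - w.groupby(level="id").transform("mean")
        R_hat = np.cov(dev.T, ddof=0) * (4 / 3)  # centering correction, k=4
        G_hat = np.cov(w.groupby(level="id").mean().T, ddof=1) - R_hat / 4
        m = BivariateBayesianLMM(responses=("a", "b"), random_state=seed,
                                 **FAST_BIV).fit(df)
        np.testing.assert_allclose(m.G_draws_.mean(0), G_hat, atol=0.08)
        np.testing.assert_allclose(m.R_draws_.mean(0), R_hat, atol=0.05)

    def test_null_pair_intervals_cover_zero(self):
        cover = 0
        for s in range(3):
            m = BivariateBayesianLMM(responses=("a", "b"), random_state=s,
                                     **FAST_BIV).fit(_pair(70 + s, 0.0, 0.0))
            c = m.correlations()
            cover += (c.r_ind_bci[0] <= 0 <= c.r_ind_bci[1]
                      and c.r_e_bci[0] <= 0 <= c.r_e_bci[1])
        assert cover >= 2

    def test_covariance_draws_symmetric_positive_definite(self):
        m = BivariateBayesianLMM(responses=("a", "b"), random_state=2,
                                 **FAST_BIV).fit(_pair(31))
        for draws in (m.G_draws_, m.R_draws_):
            assert np.allclose(draws, np.transpose(draws, (0, 2, 1)))
            assert (np.linalg.eigvalsh(draws) > 0).all()

    def test_constrained_model_has_zero_covariances(self):
        m = BivariateBayesianLMM(responses=("a", "b"), constrained=True,
                                 random_state=3, **FAST_BIV).fit(_pair(32))
        assert np.all(m.G_draws_[:, 0, 1] == 0)
        assert np.all(m.R_draws_[:, 0, 1] == 0)

    def test_bad_prior_scale_rejected(self):
        with pytest.raises(ValueError, match="positive-definite"):
            BivariateBayesianLMM(responses=("a", "b"),
                                 prior_scale=[[1.0, 2.0], [2.0, 1.0]],
                                 **FAST_BIV).fit(_pair(33))


class TestSyndrome:
    def test_degenerate_draws_reproduce_fixed_correlation(self):
        G = np.array([[[1.0, 0.65], [0.65, 1.0]]])
        R = np.array([[[1.0, 0.0], [0.0, 1.0]]])
        est = syndrome_from_draws(G, R)
        assert est.r_ind == pytest.approx(0.65)
        assert est.r_e == 0.0
        assert est.r_p == pytest.approx(0.65 / 2.0)

    def test_zero_covariances_give_zero_phenotypic_correlation(self):
        G = np.array([[[0.7, 0.0], [0.0, 0.3]]] * 4)
        R = np.array([[[1.1, 0.0], [0.0, 0.9]]] * 4)
        est = syndrome_from_draws(G, R)
        assert est.r_p == 0.0

    def test_r_p_identity_against_per_draw_formula(self, rng):
        A = rng.normal(size=(50, 2, 2))
        G = A @ np.transpose(A, (0, 2, 1)) + 0.1 * np.eye(2)
        B = rng.normal(size=(50, 2, 2))
        R = B @ np.transpose(B, (0, 2, 1)) + 0.1 * np.eye(2)
        est = syndrome_from_draws(G, R)
        direct = ((G[:, 0, 1] + R[:, 0, 1])
                  / np.sqrt((G[:, 0, 0] + R[:, 0, 0])
                            * (G[:, 1, 1] + R[:, 1, 1])))
        assert est.r_p == pytest.approx(direct.mean(), abs=1e-12)

    def test_syndrome_estimate_end_to_end_detects_signal(self):
        est = syndrome_estimate(_pair(40), responses=("a", "b"),
                                random_state=4, **FAST_BIV)
        assert est.r_ind > 0.2
        assert est.delta_dic > 2
        assert est.significant


class TestVarianceFTest:
    def test_scaling_one_group_by_two_quadruples_f(self):
        res = variance_f_test([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert res.statistic == pytest.approx(4.0)

    def test_identical_groups_give_f_one_p_one(self):
        res = variance_f_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 1.0
        assert res.pvalue == 1.0

    def test_zero_variance_denominator_flagged_infinite(self):
        res = variance_f_test([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert res.infinite
        assert np.isinf(res.statistic)

    def test_symmetric_in_argument_order(self):
        a, b = [1.0, 2.0, 4.0, 3.0], [10.0, 2.0, 5.0, 7.0]
        r1, r2 = variance_f_test(a, b), variance_f_test(b, a)
        assert r1.statistic == r2.statistic
        assert r1.pvalue == r2.pvalue
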