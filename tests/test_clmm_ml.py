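import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, spearmanr

from latentnorm import (
    CLMMSpec,
    SimulationDesign,
    fit_clmm,
    fit_thresholds_only,
    marginal_loglik_quadrature,
    ranef,
    simulate_items_only,
)
from latentnorm.clmm_ml import _OrdinalData, _laplace_loglik


def _theta(tau, sd):
    return np.concatenate(([tau[0]], np.log(np.diff(tau)), [np.log(sd)]))


class TestThresholdsOnly:
    def test_closed_form_quantiles(self):
        responses = np.repeat([1, 2, 3, 4, 5], [10, 20, 40, 20, 10])
        tau = fit_thresholds_only(responses, 5)
        expected = norm.ppf([0.1, 0.3, 0.7, 0.9])
        assert np.allclose(tau, expected, atol=1e-12)
        assert tau == pytest.approx([-1.2816, -0.5244, 0.5244, 1.2816], abs=1e-4)

    def test_uniform_counts_symmetric(self):
        responses = np.repeat([1, 2, 3, 4, 5], 20)
        tau = fit_thresholds_only(responses, 5)
        assert np.allclose(tau + tau[::-1], 0.0, atol=1e-12)

    def test_binary_reduces_to_probit_of_proportion(self):
        responses = np.repeat([1, 2], [30, 70])
        tau = fit_thresholds_only(responses, 2)
        assert tau[0] == pytest.approx(norm.ppf(0.3))

    def test_degenerate_names_category(self):
        with pytest.raises(ValueError, match="category 3"):
            fit_thresholds_only(np.full(10, 3), 5)

    def test_logit_link(self):
        from scipy.stats import logistic

        responses = np.repeat([1, 2, 3], [25, 50, 25])
        tau = fit_thresholds_only(responses, 3, link="logit")
        assert np.allclose(tau, logistic.ppf([0.25, 0.75]))


class TestQuadratureOracle:
    def test_zero_sd_equals_fixed_effects(self, small_single_factor_trials):
        tau = np.array([-1.0, -0.3, 0.4, 1.1])
        data = _OrdinalData(
            small_single_factor_trials, CLMMSpec(n_levels=5, factors=("item",))
        )
        lp, _, _ = data.loglik_terms(tau, np.zeros(data.n))
        gh = marginal_loglik_quadrature(small_single_factor_trials, tau, 0.0)
        assert gh == pytest.approx(lp.sum(), abs=1e-10)

    def test_node_count_convergence(self, small_single_factor_trials):
        tau = np.array([-1.0, -0.3, 0.4, 1.1])
        a = marginal_loglik_quadrature(small_single_factor_trials, tau, 0.8, n_nodes=20)
        b = marginal_loglik_quadrature(small_single_factor_trials, tau, 0.8, n_nodes=50)
        assert abs(a - b) < 1e-6

    def test_against_naive_monte_carlo(self, small_single_factor_trials):
        # second independent oracle: plain Monte-Carlo integration per group
        tau = np.array([-1.0, -0.3, 0.4, 1.1])
        sd = 0.8
        gh = marginal_loglik_quadrature(small_single_factor_trials, tau, sd)
        rng = np.random.default_rng(0)
        data = _OrdinalData(
            small_single_factor_trials, CLMMSpec(n_levels=5, factors=("item",))
        )
        n_mc = 200_000
        total, var_terms = 0.0, []
        from scipy.special import logsumexp

        for g in range(data.q_f["item"]):
            y = data.y[data.factor_index["item"] == g]
            b = sd * rng.standard_normal(n_mc)
            tau_pad = np.concatenate(([-np.inf], tau, [np.inf]))
            lp = np.zeros(n_mc)
            for yy in y:
                hi = tau_pad[yy] - b
                lo = tau_pad[yy - 1] - b
                lp += np.log(
                    np.clip(norm.cdf(hi) - norm.cdf(lo), 1e-300, 1.0)
                )
            log_mean = logsumexp(lp) - np.log(n_mc)
            total += log_mean
            w = np.exp(lp - lp.max())
            se_rel = w.std() / (w.mean() * np.sqrt(n_mc))
            var_terms.append(se_rel)
        mc_se = float(np.sqrt(np.sum(np.square(var_terms))))
        assert abs(gh - total) <= max(3 * mc_se, 0.02)

    def test_two_factors_rejected(self, crossed_trials):
        with pytest.raises(ValueError, match="one grouping factor"):
            marginal_loglik_quadrature(
                crossed_trials, np.array([-1.0, 0.0, 0.5, 1.0]), 1.0,
                factors=("item", "participant"),
            )


class TestLaplaceVsQuadrature:
    def test_oracle_equivalence_many_datasets(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(40):
            if checked >= 20:
                break
            design = SimulationDesign(
                n_items=10, ratings_per_item=10, seed=int(rng.integers(1 << 31))
            )
            trials = simulate_items_only(design, pattern="edge-biased")
            if trials["response"].nunique() < 5:
                continue
            tau = np.sort(rng.normal(0.0, 1.2, 4))
            if np.min(np.diff(tau)) < 0.2:
                continue
            sd = float(rng.uniform(0.2, 1.5))
            gh = marginal_loglik_quadrature(trials, tau, sd, n_nodes=50)
            data = _OrdinalData(trials, CLMMSpec(n_levels=5, factors=("item",)))
            lap = _laplace_loglik(data, _theta(tau, sd), {})
            assert abs(gh - lap) <= 0.5
            checked += 1
        assert checked >= 20

    def test_optimum_agreement(self, small_single_factor_trials):
        # optimise both surfaces over (tau1, increments, log sd); optima close
        from scipy.optimize import minimize

        trials = small_single_factor_trials
        data = _OrdinalData(trials, CLMMSpec(n_levels=5, factors=("item",)))
        theta0 = _theta(fit_thresholds_only(trials["response"], 5), 0.5)

        def neg_lap(th):
            return -_laplace_loglik(data, th, {})

        def neg_gh(th):
            tau = np.concatenate(([th[0]], th[0] + np.cumsum(np.exp(th[1:4]))))
            return -marginal_loglik_quadrature(trials, tau, np.exp(th[4]), n_nodes=20)

        opts = {"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000}
        r1 = minimize(neg_lap, theta0, method="Nelder-Mead", options=opts)
        r2 = minimize(neg_gh, theta0, method="Nelder-Mead", options=opts)
        assert np.all(np.abs(r1.x - r2.x) < 0.05)


class TestFitClmm:
    def test_zero_item_variance_recovered(self):
        design = SimulationDesign(
            n_items=50, ratings_per_item=25, sd_mu_item=0.0, seed=77,
        )
        trials = simulate_items_only(design, pattern="edge-biased")
        fit = fit_clmm(trials, CLMMSpec(n_levels=5, factors=("item",)))
        assert fit.re_sd_hat["item"] <= 0.15
        assert np.max(np.abs(fit.modes["item"])) <= 0.2

    def test_recovery_each_pattern(self):
        from latentnorm import pattern_names

        for pat in pattern_names():
            design = SimulationDesign(n_items=50, ratings_per_item=25, seed=31)
            trials = simulate_items_only(design, pattern=pat)
            fit = fit_clmm(trials, CLMMSpec(n_levels=5, factors=("item",)))
            truth = trials.groupby("item_id")["mu_item"].first()
            modes = ranef(fit, "item").set_index("level")["mode"]
            r = np.corrcoef(truth, modes[truth.index])[0, 1]
            assert r >= 0.85, pat

    def test_row_order_invariance(self, small_single_factor_trials):
        fit_a = fit_clmm(
            small_single_factor_trials, CLMMSpec(n_levels=5, factors=("item",))
        )
        shuffled = small_single_factor_trials.sample(
            frac=1.0, random_state=1
        ).reset_index(drop=True)
        fit_b = fit_clmm(shuffled, CLMMSpec(n_levels=5, factors=("item",)))
        assert np.allclose(fit_a.tau_hat, fit_b.tau_hat, atol=1e-6)
        assert np.allclose(fit_a.modes["item"], fit_b.modes["item"], atol=1e-6)

    def test_sd_floor_profiles_to_closed_form(self):
        # RE SD at the floor: profiled thresholds match the intercept-only MLE
        from scipy.optimize import minimize

        design = SimulationDesign(
            n_items=20, ratings_per_item=20, sd_mu_item=0.0, seed=9,
        )
        trials = simulate_items_only(design, pattern="edge-biased")
        data = _OrdinalData(trials, CLMMSpec(n_levels=5, factors=("item",)))
        target = fit_thresholds_only(trials["response"], 5)

        def neg(th4):
            th = np.concatenate((th4, [np.log(1e-6)]))
            return -_laplace_loglik(data, th, {})

        th0 = _theta(target, 1.0)[:4]
        res = minimize(neg, th0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10})
        tau = np.concatenate(
            ([res.x[0]], res.x[0] + np.cumsum(np.exp(res.x[1:])))
        )
        assert np.allclose(tau, target, atol=1e-4)

    def test_unknown_factor_rejected(self, small_single_factor_trials):
        with pytest.raises(ValueError, match="unknown grouping factor"):
            CLMMSpec(n_levels=5, factors=("stimulus",))

    def test_crossed_fit_recovers_both_sds(self, crossed_trials):
        fit = fit_clmm(
            crossed_trials, CLMMSpec(n_levels=5, factors=("item", "participant"))
        )
        assert fit.converged
        assert 0.6 <= fit.re_sd_hat["item"] <= 1.4
        assert 0.6 <= fit.re_sd_hat["participant"] <= 1.4


class TestRanef:
    def test_extreme_item_finite_and_largest(self):
        design = SimulationDesign(n_items=20, ratings_per_item=25, seed=15)
        trials = simulate_items_only(design, pattern="edge-biased").copy()
        items = np.sort(trials["item_id"].unique())
        trials.loc[trials["item_id"] == items[0], "response"] = 5
        fit = fit_clmm(trials, CLMMSpec(n_levels=5, factors=("item",)))
        re = ranef(fit, "item").set_index("level")["mode"]
        assert np.isfinite(re[items[0]])
        assert re[items[0]] == re.max()

    def test_rank_agreement_with_raw_means(self, items_only_trials):
        fit = fit_clmm(
            items_only_trials, CLMMSpec(n_levels=5, factors=("item",))
        )
        re = ranef(fit, "item").set_index("level")["mode"]
        raw = items_only_trials.groupby("item_id")["response"].mean()
        rho = spearmanr(re[raw.index], raw).statistic
        assert rho >= 0.95

    def test_doubling_data_reduces_shrinkage(self):
        design = SimulationDesign(n_items=15, ratings_per_item=10, seed=3)
        trials = simulate_items_only(design, pattern="equidistant")
        doubled = pd.concat([trials, trials], ignore_index=True)
        fit1 = fit_clmm(trials, CLMMSpec(n_levels=5, factors=("item",)))
        fit2 = fit_clmm(doubled, CLMMSpec(n_levels=5, factors=("item",)))
        m1 = ranef(fit1, "item").set_index("level")["mode"]
        m2 = ranef(fit2, "item").set_index("level")["mode"]
        # moving toward unshrunken values: magnitudes weakly increase overall
        assert (np.abs(m2) >= np.abs(m1) - 0.05).all()
        assert np.abs(m2).mean() > np.abs(m1).mean()

    def test_unknown_factor(self, items_only_trials):
        fit = fit_clmm(
            items_only_trials, CLMMSpec(n_levels=5, factors=("item",))
        )
        with pytest.raises(ValueError, match="participant"):
            ranef(fit, "participant")


class TestPatternInvariance:
    def test_modes_agree_across_patterns(self):
        from latentnorm import pattern_names

        design = SimulationDesign(n_items=50, ratings_per_item=25, seed=8)
        modes = {}
        for pat in pattern_names():
            trials = simulate_items_only(design, pattern=pat)
            fit = fit_clmm(trials, CLMMSpec(n_levels=5, factors=("item",)))
            modes[pat] = ranef(fit, "item").set_index("level")["mode"]
        names = list(modes)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = modes[names[i]], modes[names[j]]
                r = np.corrcoef(a, b[a.index])[0, 1]
                assert r >= 0.95, (names[i], names[j], r)


def test_likelihood_ascent_across_outer_iterates(small_single_factor_trials):
    # the outer optimiser's accepted iterates never decrease the objective
    from scipy.optimize import minimize

    trials = small_single_factor_trials
    data = _OrdinalData(trials, CLMMSpec(n_levels=5, factors=("item",)))
    theta0 = _theta(fit_thresholds_only(trials["response"], 5), 0.5)
    state = {}
    trace = []

    def neg(th):
        return -_laplace_loglik(data, th, state)

    def record(xk):
        trace.append(neg(xk))

    minimize(neg, theta0, method="L-BFGS-B", callback=record,
             options={"maxiter": 100})
    assert len(trace) >= 2
    assert np.all(np.diff(trace) <= 1e-8)


def test_fit_serialisation_roundtrip(tmp_path, small_single_factor_trials):
    import json

    fit = fit_clmm(
        small_single_factor_trials, CLMMSpec(n_levels=5, factors=("item",))
    )
    path = tmp_path / "fit.json"
    fit.to_json(path)
    payload = json.loads(path.read_text())
    assert payload["model"] == "clmm_ml"
    assert np.allclose(payload["tau_hat"], fit.tau_hat)
    assert payload["ranef"]["item"]["modes"] == fit.modes["item"].tolist()
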