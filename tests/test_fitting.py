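import numpy as np
import pytest

import pradelts as pt
from pradelts.fitting import aicc
from pradelts.likelihood import inverse_link_deriv


class TestAicc:
    def test_direct_arithmetic(self):
        assert aicc(100, 2, 1000) == pytest.approx(204.0120, abs=5e-5)

    def test_large_sample_limit_is_aic(self):
        assert aicc(100, 5, 1e12) == pytest.approx(2 * 100 + 2 * 5, abs=1e-6)

    def test_denominator_guard(self):
        with pytest.raises(ValueError):
            aicc(100, 85, 86)

    def test_monotone_in_k(self):
        vals = [aicc(50.0, k, 500) for k in range(1, 20)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestModelTable:
    def _fake(self, k, aicc_val):
        class F:
            pass

        f = F()
        f.k, f.aicc, f.converged = k, aicc_val, True
        f.name = lambda: f"m{k}"
        return f

    def test_weights_closed_form(self):
        tab = pt.model_table({"a": self._fake(2, 10.0), "b": self._fake(3, 12.0)})
        assert tab["dAICc"].tolist() == [0.0, 2.0]
        w0 = 1 / (1 + np.exp(-1))
        assert tab["weight"].to_numpy() == pytest.approx([w0, 1 - w0], abs=1e-4)

    def test_single_model_weight_one(self):
        tab = pt.model_table({"only": self._fake(2, 5.0)})
        assert tab["weight"].iloc[0] == pytest.approx(1.0)

    def test_tie_splits_weight(self):
        tab = pt.model_table({"a": self._fake(2, 7.0), "b": self._fake(4, 7.0)})
        assert tab["weight"].to_numpy() == pytest.approx([0.5, 0.5])

    def test_weights_sum_to_one_and_order_invariance(self):
        fits = {f"m{i}": self._fake(i + 1, 10.0 + 3 * i) for i in range(5)}
        tab1 = pt.model_table(fits)
        tab2 = pt.model_table(dict(reversed(list(fits.items()))))
        assert tab1["weight"].sum() == pytest.approx(1.0)
        assert tab1["model"].tolist() == tab2["model"].tolist()


class TestDeltaMethod:
    def test_logit_and_log_derivatives(self):
        # logit scale 0 +- 0.1 -> probability 0.5, SE 0.25*0.1
        assert inverse_link_deriv(0.0, "logit") * 0.1 == pytest.approx(0.025)
        # log scale 0 +- 0.1 -> rate 1.0, SE 0.1
        assert inverse_link_deriv(0.0, "log") * 0.1 == pytest.approx(0.1)

    def test_real_estimates_respect_links(self, sim_constant):
        chs = sim_constant.histories
        fit = pt.fit(chs, pt.PradelModelSpec("phi_f", {}), starts=2, seed=0)
        est = pt.real_estimates(fit)
        probs = est[est.parameter.isin(["p", "phi"])]
        assert ((probs.lcl >= 0) & (probs.ucl <= 1)).all()
        rates = est[est.parameter == "f"]
        assert (rates.lcl >= 0).all()


class TestFit:
    def test_constant_rate_recovery(self):
        # mean over a few replicates: tighter than a single 3-SE draw
        cal = pt.regular_calendar("2000-01", 10)
        reps = {p: [] for p in ("phi", "f", "p")}
        ses = {p: [] for p in ("phi", "f", "p")}
        for s in range(5):
            cfg = pt.SimulationConfig(
                seed=s, n_initial=2000, calendar=cal, phi_m=0.8, f_m=0.2, p=0.6
            )
            chs = pt.simulate_population(cfg).histories.pool_groups()
            fitted = pt.fit(chs, pt.PradelModelSpec("phi_f", {}), starts=1, seed=0)
            assert fitted.converged
            est = pt.real_estimates(fitted)
            for param in reps:
                row = est[est.parameter == param].iloc[0]
                reps[param].append(row.estimate)
                ses[param].append(row.se)
        for param, truth in (("phi", 0.8), ("f", 0.2), ("p", 0.6)):
            mean = np.mean(reps[param])
            se_mean = np.mean(ses[param]) / np.sqrt(5)
            assert abs(mean - truth) < 3 * se_mean, (param, mean, se_mean)

    def test_phi_f_and_phi_lambda_fits_agree(self, sim_constant):
        chs = sim_constant.histories.pool_groups()
        f1 = pt.fit(chs, pt.PradelModelSpec("phi_f", {}), starts=2, seed=0)
        f2 = pt.fit(chs, pt.PradelModelSpec("phi_lambda", {}), starts=2, seed=0)
        assert f1.nll == pytest.approx(f2.nll, abs=1e-6)
        r1 = f1.model.group_rates(f1.beta)[0]
        r2 = f2.model.group_rates(f2.beta)[0]
        assert r1["phi_m"] == pytest.approx(r2["phi_m"], abs=1e-4)
        assert r1["lambda_m"] == pytest.approx(r2["lambda_m"], abs=1e-4)

    def test_degenerate_boundary_flagged(self):
        # closed population, certain detection: all-ones histories, p at the
        # upper boundary; fit must not crash and must flag inestimability
        cal = pt.regular_calendar("2000-01", 3)
        cfg = pt.SimulationConfig(
            seed=0, n_initial=50, calendar=cal, phi_m=1.0, f_m=0.0, p=1.0
        )
        chs = pt.simulate_population(cfg).histories.pool_groups()
        fit = pt.fit(chs, pt.PradelModelSpec("phi_f", {}), starts=1, seed=0)
        est = pt.real_estimates(fit)
        p_row = est[est.parameter == "p"].iloc[0]
        assert p_row.estimate > 0.99

    def test_determinism_given_seed(self, sim_constant):
        chs = sim_constant.histories.pool_groups()
        a = pt.fit(chs, pt.PradelModelSpec("phi_f", {}), starts=3, seed=5)
        b = pt.fit(chs, pt.PradelModelSpec("phi_f", {}), starts=3, seed=5)
        assert a.nll == b.nll
        assert np.array_equal(a.beta, b.beta)


class TestCovariateEffect:
    def test_strong_slope_detected(self):
        cfg = pt.SimulationConfig(seed=21, n_initial=800, p=0.584)
        pop, cov, truth = pt.simulate_covariate_effect_study(cfg, {"phi:rain_sum": 0.3})
        chs = pop.histories.pool_groups()
        fit = pt.fit(
            chs, pt.PradelModelSpec("phi_f", {"phi": "~rain_sum"}),
            covariates=cov, starts=1, seed=0,
        )
        eff = pt.covariate_effect(fit, "rain_sum")
        assert eff["significant"]
        assert eff["lcl"] == pytest.approx(eff["beta"] - 1.96 * eff["se"], abs=1e-6)
        assert abs(eff["beta"] - 0.3) < 3 * eff["se"]

    def test_missing_covariate_errors(self, sim_constant):
        fit = pt.fit(
            sim_constant.histories.pool_groups(), pt.PradelModelSpec("phi_f", {}),
            starts=1, seed=0,
        )
        with pytest.raises(KeyError):
            pt.covariate_effect(fit, "rain_sum")


class TestSeniority:
    def test_constant_fit_seniority(self, sim_constant):
        chs = sim_constant.histories.pool_groups()
        fit = pt.fit(chs, pt.PradelModelSpec("phi_f", {}), starts=2, seed=0)
        sen = pt.seniority_summary(fit)
        r = fit.model.group_rates(fit.beta)[0]
        expect_m = r["phi_m"][0] / r["lambda_m"][0]
        assert sen.mean == pytest.approx(expect_m, rel=1e-10)
        assert sen.gamma == pytest.approx(sen.gamma_monthly ** chs.calendar.interval_months)
        assert (sen.survival_dominated == (sen.gamma_monthly > 0.5)).all()

    def test_closed_population_seniority_is_one(self):
        dt = np.array([5.0, 7.0])
        r = pt.map_parameterizations(dt, 0.9, lambda_m=0.9)
        assert r["gamma"] == pytest.approx([1.0, 1.0])


class TestCorrelation:
    def test_perfect_and_hand_values(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pt.correlate_series(x, x)[0] == pytest.approx(1.0)
        assert pt.correlate_series(x, -x)[0] == pytest.approx(-1.0)
        # hand computation: S_xy = 5, S_xx = 2, S_yy = 38/3
        r, p = pt.correlate_series(x, np.array([2.0, 4.0, 7.0]))
        assert r == pytest.approx(5 / np.sqrt(2 * 38 / 3), abs=1e-10)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pt.correlate_series([1, 1, 1], [1, 2, 3])
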