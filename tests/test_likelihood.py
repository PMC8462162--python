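import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pradelts as pt
from pradelts.likelihood import (
    CompiledPradelModel,
    cell_probability,
    enumerate_observable_histories,
    map_parameterizations,
)


class TestRecursions:
    def test_chi_trivial_cases(self):
        # certain detection if alive: chi_1 = Pr(dies) = 0.5
        assert pt.chi_recursion([0.5], [0.5, 1.0])[0] == pytest.approx(0.5)
        # never detectable: chi_1 = 1
        assert pt.chi_recursion([0.5], [0.5, 0.0])[0] == pytest.approx(1.0)

    def test_chi_hand_value(self):
        chi = pt.chi_recursion([0.8, 0.8], [0.9, 0.5, 0.5])
        assert chi == pytest.approx([0.44, 0.6, 1.0])

    def test_xi_trivial_cases(self):
        # gamma=1, p_1=1: must have been seen before -> xi_2 = 0
        assert pt.xi_recursion([1.0], [1.0, 0.5])[1] == pytest.approx(0.0)
        assert pt.xi_recursion([0.5], [1.0, 0.5])[1] == pytest.approx(0.5)

    def test_xi_mirrors_chi(self):
        xi = pt.xi_recursion([0.8, 0.8], [0.5, 0.5, 0.9])
        assert xi == pytest.approx([1.0, 0.6, 0.44])

    def test_relative_abundance(self):
        assert pt.relative_abundance([1, 1, 1]) == pytest.approx([1, 1, 1, 1])
        assert pt.relative_abundance([2, 0.5]) == pytest.approx([1, 2, 1])
        lam = [0.993**5] * 3
        assert pt.relative_abundance(lam)[3] == pytest.approx(0.993**15)
        with pytest.raises(ValueError):
            pt.relative_abundance([1.0, -0.1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pt.chi_recursion([1.5], [0.5, 0.5])
        with pytest.raises(ValueError):
            pt.xi_recursion([-0.1], [0.5, 0.5])


class TestCellProbabilities:
    def test_two_occasion_uniform_thirds(self):
        # p=1 everywhere, Phi=0.5, gamma=0.5 (Lambda=1): each observable
        # history has mass 1/3 (C = 1.5)
        for h in ([1, 1], [1, 0], [0, 1]):
            assert cell_probability(h, [1, 1], [0.5], [0.5]) == pytest.approx(1 / 3)

    def test_no_recruitment_blocks_late_entry(self):
        assert cell_probability([0, 1], [1, 1], [0.7], [1.0]) == pytest.approx(0.0)

    def test_enumeration_sums_to_one_fixed(self):
        H = enumerate_observable_histories(4)
        lp = pt.cell_log_probabilities(H, [0.5] * 4, [0.8] * 3, [0.7] * 3)
        assert np.exp(lp).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_history_rejected(self):
        with pytest.raises(ValueError):
            cell_probability([0, 0], [0.5, 0.5], [0.5], [0.5])

    @settings(deadline=None, max_examples=40)
    @given(
        T=st.integers(2, 6),
        seed=st.integers(0, 10_000),
    )
    def test_enumeration_sums_to_one_randomized(self, T, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.05, 0.95, T)
        Phi = rng.uniform(0.05, 0.95, T - 1)
        gamma = rng.uniform(0.05, 0.95, T - 1)
        H = enumerate_observable_histories(T)
        total = np.exp(pt.cell_log_probabilities(H, p, Phi, gamma)).sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(T=st.integers(2, 5), seed=st.integers(0, 10_000))
    def test_temporal_symmetry_duality(self, T, seed):
        # reversing histories while swapping the roles of survival and
        # seniority leaves every conditional cell probability unchanged
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.05, 0.95, T)
        Phi = rng.uniform(0.05, 0.95, T - 1)
        gamma = rng.uniform(0.05, 0.95, T - 1)
        H = enumerate_observable_histories(T)
        lp = pt.cell_log_probabilities(H, p, Phi, gamma)
        lp_rev = pt.cell_log_probabilities(
            H[:, ::-1], p[::-1], gamma[::-1], Phi[::-1]
        )
        assert np.max(np.abs(lp - lp_rev)) < 1e-10

    def test_matches_simulated_frequencies(self):
        # generative cross-check: empirical conditional pattern frequencies
        # from the population simulator approach the cell probabilities
        cal = pt.regular_calendar("2000-01", 3)
        cfg = pt.SimulationConfig(
            seed=3, n_initial=40_000, calendar=cal, phi_m=0.7, f_m=0.3, p=0.5
        )
        pop = pt.simulate_population(cfg)
        chs = pop.histories.pool_groups()
        rates = map_parameterizations(cal.interval_months, 0.7, f_m=0.3)
        emp = chs.counts[:, 0] / chs.total_individuals()
        model = np.exp(
            pt.cell_log_probabilities(
                chs.histories, np.full(3, 0.5), rates["Phi"], rates["gamma"]
            )
        )
        assert np.max(np.abs(emp - model)) < 0.01


class TestParameterizationMaps:
    def test_additive_identity(self):
        r = map_parameterizations(np.array([1.0]), 0.789, f_m=0.175)
        assert r["lambda_m"][0] == pytest.approx(0.964)

    def test_annual_scaling(self):
        r = map_parameterizations(np.array([12.0]), 0.789, f_m=0.175)
        assert r["Phi"][0] == pytest.approx(0.058, abs=5e-4)
        assert round(float(r["Phi"][0]), 3) == 0.058

    def test_seniority_map(self):
        r = map_parameterizations(np.array([5.0]), 0.789, lambda_m=0.964)
        assert r["gamma"][0] == pytest.approx((0.789 / 0.964) ** 5, rel=1e-12)

    def test_inverse_consistency(self):
        dt = np.array([7.0, 5.0])
        via_f = map_parameterizations(dt, 0.8, f_m=0.15)
        via_lam = map_parameterizations(dt, 0.8, lambda_m=0.95)
        via_gam = map_parameterizations(dt, 0.8, gamma_m=via_f["gamma_m"][0])
        for key in ("Phi", "Lambda", "gamma", "f_m"):
            assert via_f[key] == pytest.approx(via_lam[key], rel=1e-10)
            assert via_f[key] == pytest.approx(via_gam[key], rel=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            map_parameterizations(np.array([1.0]), 0.8, f_m=-0.1)
        with pytest.raises(ValueError):
            map_parameterizations(np.array([1.0]), 0.8)


class TestNegLogLik:
    def test_iid_doubling(self, short_calendar):
        from pradelts.histories import CaptureHistorySet

        h = np.array([[1, 0, 1, 0, 0, 0]], dtype=np.int8)
        one = CaptureHistorySet(h, np.array([[1]]), ["all"], short_calendar)
        two = CaptureHistorySet(h, np.array([[2]]), ["all"], short_calendar)
        spec = pt.PradelModelSpec("phi_f", {})
        beta = np.array([0.2, -0.1, np.log(0.2)])
        assert pt.negloglik(two, spec, beta) == pytest.approx(
            2 * pt.negloglik(one, spec, beta), rel=1e-12
        )

    def test_known_two_occasion_value(self):
        from pradelts.histories import CaptureHistorySet

        cal = pt.regular_calendar("2000-01", 2)
        chs = CaptureHistorySet(np.array([[1, 1]]), np.array([[1]]), ["all"], cal)
        # p=1, Phi=0.5, gamma=0.5 -> Pr(11) = 1/3
        lp = pt.cell_log_probabilities(chs.histories, [1, 1], [0.5], [0.5])
        assert -lp[0] == pytest.approx(np.log(3.0), rel=1e-12)

    def test_parameterization_equivalence_at_mapped_point(self, sim_constant):
        chs = sim_constant.histories.pool_groups()
        phi_m, f_m = 0.8, 0.18
        lam_m = phi_m + f_m
        gam_m = phi_m / lam_m
        from pradelts.likelihood import link_fn

        nlls = []
        for par, val, link in (
            ("phi_f", f_m, "log"),
            ("phi_lambda", lam_m, "log"),
            ("phi_gamma", gam_m, "logit"),
        ):
            spec = pt.PradelModelSpec(par, {})
            beta = np.array([0.0, link_fn(phi_m, "logit"), link_fn(val, link)])
            m = CompiledPradelModel(chs, spec)
            # beta order is (phi, second, p); build accordingly
            beta = np.array([link_fn(phi_m, "logit"), link_fn(val, link), 0.0])
            nlls.append(m.nll(beta))
        assert np.ptp(nlls) < 1e-9 * max(nlls)

    def test_monthly_equals_interval_when_dt_one(self, sim_monthly):
        chs = sim_monthly.histories.pool_groups()
        spec = pt.PradelModelSpec("phi_f", {})
        m = CompiledPradelModel(chs, spec)
        beta = np.array([0.5, np.log(0.2), 0.1])
        rates = m.group_rates(beta)[0]
        assert rates["Phi"] == pytest.approx(rates["phi_m"])
        assert rates["Lambda"] == pytest.approx(rates["lambda_m"])
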