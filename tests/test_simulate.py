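import numpy as np
import pytest

import pradelts as pt


class TestPopulationSimulator:
    def test_closed_census(self):
        cal = pt.regular_calendar("2000-01", 5)
        cfg = pt.SimulationConfig(
            seed=1, n_initial=80, calendar=cal, phi_m=1.0, f_m=0.0, p=1.0
        )
        pop = pt.simulate_population(cfg)
        assert (pop.realized_n == 80).all()
        assert pop.detections.shape == (80, 5)
        assert pop.detections.all()

    def test_negative_recruitment_rejected(self):
        with pytest.raises(ValueError):
            pt.simulate_population(pt.SimulationConfig(seed=0, f_m=-0.01))

    def test_determinism_and_inp_bytes(self, tmp_path):
        cal = pt.occasion_calendar("1993-10", "1996-05")
        out = []
        for _ in range(2):
            pop = pt.simulate_population(
                pt.SimulationConfig(seed=9, n_initial=150, calendar=cal)
            )
            path = tmp_path / f"{len(out)}.inp"
            pt.write_inp(pop.histories, path)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_stationary_growth(self):
        # lambda_m = 1 exactly: expected terminal size equals initial size
        cal = pt.regular_calendar("2000-01", 8)
        ratios = []
        for s in range(40):
            cfg = pt.SimulationConfig(
                seed=s, n_initial=500, calendar=cal, phi_m=0.8, f_m=0.2, p=0.5
            )
            pop = pt.simulate_population(cfg)
            ratios.append(pop.realized_n[-1] / pop.realized_n[0])
        mean = np.mean(ratios)
        mc_se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(mean - 1.0) < 3 * mc_se + 0.01

    def test_expected_growth_per_interval(self):
        # E[N_{t+1} | N_t] = N_t lambda_m^{dt}
        cal = pt.occasion_calendar("1993-10", "1994-05")
        lam = 0.9
        vals = []
        for s in range(60):
            cfg = pt.SimulationConfig(
                seed=s, n_initial=800, calendar=cal, phi_m=0.8, f_m=lam - 0.8, p=0.5
            )
            pop = pt.simulate_population(cfg)
            vals.append(pop.realized_n[1] / 800)
        expect = lam**7
        assert np.mean(vals) == pytest.approx(expect, abs=3 * np.std(vals) / np.sqrt(60) + 1e-3)

    def test_study_scale_marked_count(self):
        pop = pt.simulate_population(pt.SimulationConfig(seed=4))
        assert 2000 < pop.n_marked() < 4500

    def test_histories_round_trip_through_capture_data(self, tmp_path):
        pop = pt.simulate_population(
            pt.SimulationConfig(
                seed=2, n_initial=100, calendar=pt.occasion_calendar("1993-10", "1996-05")
            )
        )
        chs = pop.histories
        path = tmp_path / "sim.inp"
        pt.write_inp(chs, path)
        assert pt.read_inp(path, group_count=2, calendar=chs.calendar).equals(chs)
        # records table rebuilds the same histories
        rec = pt.records_from_population(pop)
        rebuilt = pt.build_histories(rec, chs.calendar)
        assert rebuilt.select_groups(["F", "M"]).equals(chs.canonical())


class TestWeatherSimulator:
    def test_no_wet_days_means_no_rain(self):
        cfg = pt.SimulationConfig(
            seed=0, calendar=pt.occasion_calendar("1993-10", "1995-10"),
            wet_day_prob={"winter": 0.0, "summer": 0.0},
        )
        w = pt.simulate_weather(cfg)
        assert (w.prcp == 0).all()

    def test_determinism(self):
        cfg = pt.SimulationConfig(seed=3, calendar=pt.occasion_calendar("1993-10", "1995-10"))
        a = pt.simulate_weather(cfg)
        b = pt.simulate_weather(cfg)
        assert a.equals(b)

    def test_seasonal_rainfall_calibration(self):
        # many simulated seasons: mean monthly totals near the configured
        # Mediterranean targets (5.26 cm winter months, 0.33 summer)
        wint, summ = [], []
        for s in range(25):
            cfg = pt.SimulationConfig(seed=s)
            tab = pt.seasonal_aggregate(pt.simulate_weather(cfg), cfg.calendar)
            wint += (tab[tab.season == "winter"].rain_sum / 7).tolist()
            summ += (tab[tab.season == "summer"].rain_sum / 5).tolist()
        assert np.mean(wint) == pytest.approx(5.26, rel=0.05)
        assert np.mean(summ) == pytest.approx(0.33, rel=0.05)

    def test_temperature_seasonality(self):
        cfg = pt.SimulationConfig(seed=5, calendar=pt.occasion_calendar("1993-10", "1995-10"))
        tab = pt.seasonal_aggregate(pt.simulate_weather(cfg), cfg.calendar)
        assert (
            tab[tab.season == "summer"].temp_avg.mean()
            > tab[tab.season == "winter"].temp_avg.mean() + 5
        )


class TestCovariateEffectStudy:
    def test_truth_record_consistency(self):
        cfg = pt.SimulationConfig(seed=8, n_initial=200,
                                  calendar=pt.occasion_calendar("1993-10", "1999-05"))
        pop, cov, truth = pt.simulate_covariate_effect_study(cfg, {"phi:rain_sum": 0.2})
        assert set(cov.columns) == {"rain_sum"}
        assert cov["rain_sum"].mean() == pytest.approx(0.0, abs=1e-12)
        from pradelts.likelihood import inverse_link, link_fn

        expect = inverse_link(
            link_fn(0.789, "logit") + 0.2 * cov["rain_sum"].to_numpy(), "logit"
        )
        assert pop.truth["phi_m"] == pytest.approx(expect)

    def test_out_of_range_rates_rejected(self):
        cfg = pt.SimulationConfig(seed=9, n_initial=50,
                                  calendar=pt.occasion_calendar("1993-10", "1996-05"))
        with pytest.raises(ValueError, match="survival"):
            pt.simulate_covariate_effect_study(
                cfg, {"f:temp_avg": 0.0}, baseline={"phi_m": 1.5, "f_m": 0.2}
            )
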