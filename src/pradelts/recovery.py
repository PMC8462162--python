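"""Parameter-recovery studies at the study's design scale.

Each function simulates capture histories under known rates on the full
biannual design (42 occasions, alternating 7/5-month intervals, roughly
three thousand marked adults), fits the corresponding model and returns
the estimates with their SEs alongside the generating truth.  These are
the verification experiments the acceptance checks and the analysis
scripts run.
"""

from __future__ import annotations

import numpy as np

from .design import PradelModelSpec
from .fitting import fit, model_table, real_estimates
from .popan import fit_popan
from .calendar import regular_calendar, occasion_calendar
from .simulate import (
    SimulationConfig,
    simulate_covariate_effect_study,
    simulate_population,
    simulate_superpopulation,
)

#: overall / sex / season monthly rates used as generating truth
OVERALL = {"phi_m": 0.789, "f_m": 0.175, "p": 0.584}
SEX_P = {"F": 0.700, "M": 0.468}
SEASON = {
    "phi_m": {"winter": 0.848, "summer": 0.764},
    "f_m": {"winter": 0.137, "summer": 0.240},
    "p": {"winter": 0.526, "summer": 0.641},
}

_MOD = 2**31 - 1


def subseed(seed: int, k: int) -> int:
    """Derived stream seed, kept below 2^31."""
    return (seed * 1_000_003 + k) % _MOD


def _est(df, param, index=1, group=None):
    sub = df[df.parameter == param]
    if group is not None:
        sub = sub[sub.group == group]
    row = sub[sub["index"] == index].iloc[0]
    return float(row.estimate), float(row.se)


def recover_constant(seed: int, n_initial: int = 1200) -> dict:
    """Constant phi-f and phi-lambda fits on one overall-rate simulation."""
    cfg = SimulationConfig(seed=seed, n_initial=n_initial, p=OVERALL["p"])
    pop = simulate_population(cfg)
    chs = pop.histories.pool_groups()
    f_fit = fit(chs, PradelModelSpec("phi_f", {}), starts=3, seed=seed)
    l_fit = fit(chs, PradelModelSpec("phi_lambda", {}), starts=3, seed=seed)
    ef = real_estimates(f_fit)
    el = real_estimates(l_fit)
    phi, phi_se = _est(ef, "phi")
    f, f_se = _est(ef, "f")
    lam, lam_se = _est(el, "lambda")
    return {
        "n_marked": pop.n_marked(),
        "phi": phi, "phi_se": phi_se, "phi_truth": OVERALL["phi_m"],
        "f": f, "f_se": f_se, "f_truth": OVERALL["f_m"],
        "lambda": lam, "lambda_se": lam_se,
        "lambda_truth": OVERALL["phi_m"] + OVERALL["f_m"],
        "lambda_equals_phi_plus_f_gap": abs(lam - (phi + f)),
        "converged": bool(f_fit.converged and l_fit.converged),
    }


def recover_sex(seed: int, n_initial: int = 1200) -> dict:
    """p(~sex) fit on a two-sex simulation with the published sex-specific
    capture probabilities and shared vital rates."""
    cfg = SimulationConfig(seed=seed, n_initial=n_initial, p=dict(SEX_P))
    pop = simulate_population(cfg)
    fitted = fit(pop.histories, PradelModelSpec("phi_f", {"p": "~sex"}),
                 starts=3, seed=seed)
    est = real_estimates(fitted)
    pf, pf_se = _est(est, "p", group="F")
    pm, pm_se = _est(est, "p", group="M")
    return {
        "n_marked": pop.n_marked(),
        "p_female": pf, "p_female_se": pf_se, "p_female_truth": SEX_P["F"],
        "p_male": pm, "p_male_se": pm_se, "p_male_truth": SEX_P["M"],
        "converged": bool(fitted.converged),
    }


def recover_season(seed: int, n_initial: int = 300) -> dict:
    """phi(~season) p(~season) f(~season) fit on a season-structured
    simulation (7-month winters, 5-month summers)."""
    cfg = SimulationConfig(
        seed=seed, n_initial=n_initial,
        phi_m=dict(SEASON["phi_m"]), f_m=dict(SEASON["f_m"]), p=dict(SEASON["p"]),
    )
    pop = simulate_population(cfg)
    chs = pop.histories.pool_groups()
    spec = PradelModelSpec("phi_f", {"phi": "~season", "p": "~season", "f": "~season"})
    fitted = fit(chs, spec, starts=3, seed=seed)
    est = real_estimates(fitted)
    # interval 1 is a winter (opens with the October session), interval 2 a summer
    phi_w, phi_w_se = _est(est, "phi", index=1)
    phi_s, phi_s_se = _est(est, "phi", index=2)
    f_w, f_w_se = _est(est, "f", index=1)
    f_s, f_s_se = _est(est, "f", index=2)
    return {
        "n_marked": pop.n_marked(),
        "phi_winter": phi_w, "phi_winter_se": phi_w_se,
        "phi_winter_truth": SEASON["phi_m"]["winter"],
        "phi_summer": phi_s, "phi_summer_se": phi_s_se,
        "phi_summer_truth": SEASON["phi_m"]["summer"],
        "f_winter": f_w, "f_winter_se": f_w_se,
        "f_winter_truth": SEASON["f_m"]["winter"],
        "f_summer": f_s, "f_summer_se": f_s_se,
        "f_summer_truth": SEASON["f_m"]["summer"],
        "converged": bool(fitted.converged),
    }


def constant_rate_bias_study(seed: int, n_reps: int = 100, n_initial: int = 1200) -> dict:
    """Replicated constant-rate recovery: mean phi, f and lambda estimates
    with Monte-Carlo SEs against the generating truth.

    The replicate mean is the right check for lambda: a single fit's
    conditional SE reflects sampling noise given the realized trajectory,
    not the demographic process variance between trajectories.
    """
    out = []
    for r in range(n_reps):
        cfg = SimulationConfig(
            seed=subseed(seed, r), n_initial=n_initial, p=OVERALL["p"]
        )
        chs = simulate_population(cfg).histories.pool_groups()
        fitted = fit(chs, PradelModelSpec("phi_f", {}), starts=1, seed=seed,
                     compute_vcov=False)
        rates = fitted.model.group_rates(fitted.beta)[0]
        out.append([rates["phi_m"][0], rates["f_m"][0], rates["lambda_m"][0]])
    arr = np.asarray(out)
    res = {"n_reps": n_reps}
    for i, name in enumerate(("phi", "f", "lambda")):
        res[f"{name}_mean"] = float(arr[:, i].mean())
        res[f"{name}_mc_se"] = float(arr[:, i].std(ddof=1) / np.sqrt(n_reps))
    res["phi_truth"] = OVERALL["phi_m"]
    res["f_truth"] = OVERALL["f_m"]
    res["lambda_truth"] = OVERALL["phi_m"] + OVERALL["f_m"]
    return res


def slope_study(
    seed: int,
    param: str,
    covariate: str,
    slope: float,
    n_reps: int = 100,
    n_initial: int = 1200,
) -> dict:
    """Replicated recovery of a link-scale covariate slope on phi or f.

    Each replicate draws a fresh z-scored covariate and population, fits
    the single-covariate model and records the slope MLE; returns the mean
    estimate and its Monte-Carlo standard error.
    """
    betas = []
    for r in range(n_reps):
        cfg = SimulationConfig(
            seed=subseed(seed, r), n_initial=n_initial, p=OVERALL["p"]
        )
        pop, cov, _ = simulate_covariate_effect_study(cfg, {f"{param}:{covariate}": slope})
        chs = pop.histories.pool_groups()
        spec = PradelModelSpec("phi_f", {param: f"~{covariate}"})
        fitted = fit(chs, spec, covariates=cov, starts=1, seed=seed,
                     compute_vcov=False)
        betas.append(fitted.beta[fitted.beta_names.index(f"{param}:{covariate}")])
    betas = np.asarray(betas)
    return {
        "mean_beta": float(betas.mean()),
        "mc_se": float(betas.std(ddof=1) / np.sqrt(len(betas))),
        "sd": float(betas.std(ddof=1)),
        "truth": slope,
        "n_reps": n_reps,
    }


def popan_bias_study(
    seed: int, n_reps: int = 200, n_super: int = 2000, T: int = 8,
    p: float = 0.5, phi: float = 0.85,
) -> dict:
    """Replicated POPAN recovery: mean relative bias of the occasion
    abundance estimates against each replicate's realized abundance."""
    cal = regular_calendar("2000-01", T)
    rel = []
    for r in range(n_reps):
        pop = simulate_superpopulation(cal, n_super, p=p, phi_interval=phi,
                                       seed=subseed(seed, r))
        chs = pop.histories.pool_groups()
        m = fit_popan(chs, starts=1, seed=seed, compute_vcov=False)
        rel.append((m.abundance.N.to_numpy() - pop.realized_n) / pop.realized_n)
    rel = np.asarray(rel)
    return {
        "mean_relative_bias": float(rel.mean()),
        "max_abs_occasion_bias": float(np.abs(rel.mean(axis=0)).max()),
        "n_reps": n_reps,
    }


def season_selection_study(
    seed: int, n_reps: int = 50, n_initial: int = 250, end: str = "2003-05"
) -> dict:
    """AICc power check: how often season-structured truth makes the
    seasonal model beat the constant model by more than 2 AICc units."""
    cal = occasion_calendar("1993-10", end)
    wins = 0
    season_spec = PradelModelSpec(
        "phi_f", {"phi": "~season", "p": "~season", "f": "~season"}
    )
    const_spec = PradelModelSpec("phi_f", {})
    for r in range(n_reps):
        cfg = SimulationConfig(
            seed=subseed(seed, r), n_initial=n_initial, calendar=cal,
            phi_m=dict(SEASON["phi_m"]), f_m=dict(SEASON["f_m"]), p=dict(SEASON["p"]),
        )
        chs = simulate_population(cfg).histories.pool_groups()
        fits = {
            "season": fit(chs, season_spec, starts=1, seed=seed, compute_vcov=False),
            "constant": fit(chs, const_spec, starts=1, seed=seed, compute_vcov=False),
        }
        tab = model_table(fits)
        if tab["model"].iloc[0] == "season" and tab["dAICc"].iloc[1] > 2:
            wins += 1
    return {"prop_season_preferred": wins / n_reps, "n_reps": n_reps}
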