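# pradelts

Temporal-symmetry capture–mark–recapture analysis for a biannually
trapped small-mammal population, built around the demographic question:
how much do survival and recruitment each contribute to realized
population growth, and how does climate drive them?

The package implements Pradel's temporal-symmetry model for individual
encounter histories collected in May and October sessions with unequal
seasonal intervals (7-month wet winters, 5-month dry summers), in three
parameterizations (φ–f, φ–λ, φ–γ), together with:

- MARK-style `.inp` encounter-history I/O and history construction from
  long-format capture records (adults only, sexes as groups);
- formula-based design matrices (`~time`, `~season + sex`,
  `~season * sex`, numeric climate covariates, sampling-area indicator)
  on logit/log link scales;
- AICc model selection with Akaike weights, delta-method real-scale
  estimates, covariate-slope inference, and seniority (γ) summaries;
- POPAN (Jolly–Seber superpopulation) occasion-abundance estimation;
- per-interval climate covariates from daily weather (seasonal means,
  CVs, totals, one-season lags) and ONI/ENSO episode classification;
- a synthetic-data generator that emulates the full study design and
  Mediterranean weather, so every estimator is verified by parameter
  recovery against known truth.

## The model

For occasions `t = 1..T` with interval lengths `Δt` months, monthly
apparent survival `φ_m` and monthly per-capita recruitment `f_m` combine
into monthly realized growth `λ_m = φ_m + f_m`. Interval-scale quantities
are `Φ_t = φ_m^Δt`, `Λ_t = λ_m^Δt`, and the seniority probability — the
reverse-time chance that an animal present at `t+1` was already present
at `t` — is `γ_{t+1} = Φ_t / Λ_t`. With `r_t` the expected abundance
relative to occasion 1 (`r_{t+1} = r_t Λ_t`), `ξ_t` the probability of no
detection before `t`, and `χ_t` the probability of no detection after
`t`, a history first seen at `a` and last seen at `b` has probability,
conditional on being seen at least once,

```
Pr(h) = r_a ξ_a p_a [ Π_{t=a}^{b-1} Φ_t p_{t+1}^{y}(1-p_{t+1})^{1-y} ] χ_b / C,
C = Σ_t r_t ξ_t p_t .
```

γ > 0.5 means survival contributes more to growth than recruitment.
Abundance comes from the POPAN superpopulation model: entry proportions
`pent` allocate `N_super` animals to arrival occasions and
`N_t = N_super ψ_t` with `ψ_{t+1} = ψ_t Φ_t + pent_{t+1}`.

## Worked example

```python
import pradelts as pt

# study design: Oct 1993 .. May 2014, 42 occasions, intervals 7,5,7,...
cfg = pt.SimulationConfig(seed=2, n_initial=1200, p=0.584)
pop = pt.simulate_population(cfg)
chs = pop.histories.pool_groups()
print(pop.n_marked())                       # 3062 marked adults

fit = pt.fit(chs, pt.PradelModelSpec("phi_f", {}), starts=3, seed=0)
est = pt.real_estimates(fit).drop_duplicates("parameter")
print(est[["parameter", "estimate", "se"]].round(4).to_string(index=False))
```

prints

```
parameter  estimate     se
      phi    0.7889 0.0059
        f    0.1762 0.0059
        p    0.6053 0.0319
```

From histories simulated with monthly survival 0.789, recruitment 0.175
and capture probability 0.584, the constant φ–f fit recovers the two
vital rates to within one standard error (the capture estimate sits
within one of its larger SEs). `pt.seniority_summary(fit)` then reports
mean monthly γ = 0.817: about 82% of animals present in a month survived
from the previous month, so survival dominates realized growth.

## The analysis pipeline

Numbered drivers under `analysis/` rebuild the full workflow on a
synthetic study (each writes tables under `results/`):

1. `01_simulate_study.py` — generate histories (`.inp`), capture
   records, calendar, daily weather, ONI series and the truth record;
2. `02_base_models.py` — fit the base candidate structures (time,
   season, sex), rank by AICc, test the 1997 sampling-area change;
3. `03_covariate_effects.py` — build per-interval climate covariates
   and fit single-covariate models per vital rate (slopes per SD);
4. `04_seniority_growth.py` — time-specific vital-rate series, first
   growth estimate omitted, seniority summary;
5. `05_popan_abundance.py` — POPAN abundance by era with SEs, compared
   against the simulation's true alive counts.

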