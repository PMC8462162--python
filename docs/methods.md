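# Methods

## Model

The likelihood engine implements the temporal-symmetry (Pradel) model for
binary encounter histories, conditional on each animal being detected at
least once. Forward in time, an animal alive at occasion `t` survives the
following interval with probability `Φ_t` and, if alive at `t+1`, is
detected with probability `p_{t+1}`. Backward in time, an animal present
at `t+1` was already present at `t` with seniority probability
`γ_{t+1}`; the two directions are tied together by the realized growth
rate `Λ_t = Φ_t / γ_{t+1}` and per-capita recruitment `F_t = Λ_t − Φ_t`.

Three quantities drive the cell probabilities:

- `χ_t` (forward): probability of no detection after `t` given alive at
  `t`; `χ_T = 1`, `χ_t = (1−Φ_t) + Φ_t (1−p_{t+1}) χ_{t+1}`;
- `ξ_t` (reverse): probability of no detection before `t` given present
  at `t`; `ξ_1 = 1`, `ξ_t = (1−γ_t) + γ_t (1−p_{t−1}) ξ_{t−1}`;
- `r_t`: abundance at `t` relative to occasion 1, `r_{t+1} = r_t Λ_t`.

A history first detected at `a` and last detected at `b` has conditional
probability `r_a ξ_a p_a [Π_{t=a}^{b−1} Φ_t p^y (1−p)^{1−y}] χ_b / C`
with normalizer `C = Σ_t r_t ξ_t p_t`. Two structural properties verify
this form and are enforced as tests: the probabilities of all `2^T − 1`
observable histories sum to one (checked to 1e−12 by enumeration for
T ≤ 6 at randomized parameters), and reversing every history while
swapping the roles of `Φ` and `γ` (with `p` reversed) leaves every cell
probability unchanged — the temporal symmetry that gives the model its
name. A generative cross-check compares the cell probabilities against
empirical history frequencies from the independent population simulator.

## Unequal intervals and parameterizations

All vital rates are modelled on the monthly scale and raised to the
interval length in months (`Δt` alternates 7 and 5 in the biannual
design): `Φ_t = φ_m^{Δt}`, `Λ_t = λ_m^{Δt}`, hence
`γ_{t+1} = (φ_m/λ_m)^{Δt}`. Recruitment is derived on the monthly scale
as `f_m = λ_m − φ_m` (no fractional powers of interval recruitment).
The three parameterizations — φ–f, φ–λ, φ–γ — are exact reparameteriza-
tions of the same likelihood and agree in NLL to optimizer precision;
this equivalence is asserted in tests. Links: logit for `p`, `φ_m` and
monthly `γ`; log for `f_m` and `λ_m` (which keeps recruitment
nonnegative and growth positive by construction).

Seniority is reported on the monthly scale (`γ_m = φ_m/λ_m`, the
proportion of animals present in a month that survived from the previous
month); the interval-scale series `γ_m^{Δt}` is returned alongside. At
5–7-month intervals the two differ substantially (0.82 monthly ≈ 0.3 per
interval), and the monthly scale is the one on which "γ > 0.5 means
survival dominates growth" is interpreted here.

## Design matrices

Each parameter carries a small Wilkinson formula over `1`, `time`,
`year`, `season`, `sex`, `area` and named numeric covariates, with `+`
(additive) and `*` (main effects plus interaction). A `time` or `year`
term absorbs the intercept with one column per level; other factors are
treatment-coded. On the 42-occasion calendar this reproduces the
conventional parameter counts: `φ(~time) p(~season+sex) f(~time)` has
K = 41 + 3 + 41 = 85. K is reported as the naive column count; a
separate estimable-parameter count comes from the rank of the observed
information, since fully time-specific models confound terminal and
initial parameters. For time-specific fits the first realized-growth
estimate is omitted from reports (confounded with initial entry).
Numeric covariates are z-scored before entering the design (slopes read
per SD); raw-scale fitting is available by flag.

## Estimation

The negative log-likelihood is minimized on the link scale with
L-BFGS-B from multiple starts: probability intercepts at logit(0.5),
recruitment at log(0.15), growth at log(1), slopes at 0, with N(0, 0.5²)
jitter on subsequent starts (5 by default, deterministic given the
seed). Gradients are finite-difference; because 2-point FD noise scales
with the objective (roundoff ≈ |NLL|·ε/h, O(0.1) at |NLL| ≈ 1e4),
convergence is declared when the optimizer terminates successfully and
the projected gradient satisfies max|g| ≤ 1e−4 · max(1, |NLL|).
Covariances are inverse observed-information (numerical Hessian,
symmetrized); a rank-deficient Hessian flags the fit and falls back to a
pseudo-inverse. Real-scale estimates use the delta method; confidence
intervals are computed on the link scale and back-transformed, so they
respect parameter ranges. An estimate is flagged inestimable when its
95% CI spans essentially the whole (0,1) range or its link-scale SE
exceeds 10. Probabilities are floored at 1e−300 before logs and cell
probabilities accumulate in log space.

AICc uses `2·NLL + 2K + 2K(K+1)/(ESS − K − 1)` with the effective sample
size defaulting to the total number of detections (the number of
distinct individuals is selectable); only comparisons within one ESS
convention are meaningful. Model weights are the usual normalized
`exp(−Δ/2)`. Covariate significance is CI-exclusion of zero at 95%,
with no multiple-testing correction.

## POPAN abundance

The superpopulation model uses the full likelihood: a binomial term for
observing `n` of `N_super` animals — with Pr(never detected) from the
entry-weighted recursion `ν_t = (1−p_t)[(1−Φ_t) + Φ_t ν_{t+1}]` — and
per-history terms mixing over unobserved entry occasions through
`ω_{a+1} = pent_{a+1} + ω_a (1−p_a) Φ_a`. Entry proportions are
occasion-specific on a multinomial-logit scale (summing to one by
construction); survival may follow any interval-level formula and is
Δt-scaled as in the Pradel engine. Internally `N_super` is parameterized
as `n + exp(θ)`, which enforces the constraint that the superpopulation
is at least the observed count; the likelihood itself also rejects
`N_super < n`. Occasion abundances `N_t = N_super ψ_t`
(`ψ_{t+1} = ψ_t Φ_t + pent_{t+1}`) get delta-method SEs via a numerical
Jacobian. Sexes are pooled by default (abundance series are totals);
per-sex fits are obtained by subsetting groups. When the calendar
contains the October 1997 design change, the pipeline fits the two eras
separately; with season-structured truth, survival should be modelled
`~season` — a constant monthly survival induces alternating seasonal
bias in the abundance series.

## Climate covariates

An interval's weather window runs from the month of its opening session
through the month before its closing session (October–April for a
winter, May–September for a summer, matching the 7/5-month interval
lengths). Covariates per interval: mean daily temperature, CVs of daily
temperature and rainfall (sample SD over mean; zero-rain days included),
total rainfall, each also with a one-season lag (an exact shift, missing
for the first interval and mean-imputed — zero after z-scoring — when a
lagged model is fitted), and the mean of the ONI 3-month values whose
center months overlap the window. ENSO episodes require at least five
consecutive 3-month values at or beyond ±0.5 °C (threshold inclusive,
the NOAA convention). CVs are computed from daily records by default;
monthly aggregation is available by flag.

## Synthetic data

The simulator mirrors the model's own semantics: alive animals survive
interval `t` with `φ_m(t)^{Δt}`; recruits arrive Poisson with mean
`N_t (λ_m^{Δt} − φ_m^{Δt})` and enter just before the next occasion (so
they are detectable at entry); detection is Bernoulli with sex- and
occasion-specific probability; sex is assigned 50/50 independent of
demography. Defaults reproduce the study conditions: 42 occasions
(October 1993 – May 2014), monthly survival 0.789 and recruitment 0.175,
sex-specific capture probabilities 0.700/0.468, and an initial abundance
of 1,200, chosen by pilot calculation so the expected number of marked
adults is near three thousand. Daily weather is a wet-day Bernoulli ×
exponential-amount process calibrated so expected monthly rainfall
matches the seasonal targets (5.26 cm winter, 0.33 cm summer), plus a
sinusoidal-with-noise temperature. Covariate-effect studies draw
z-scored standard-normal covariates and apply link-scale slopes to the
monthly rates, recording the full truth for recovery tests.

What the simulator does **not** emulate: spatial structure (trapping
grids, movement, density dependence), individual heterogeneity in
capture or survival, within-session (nightly) capture dynamics, age
structure, or observation-level weather error. Passing recovery tests
therefore demonstrates correctness of the estimators under the model's
own assumptions at the study's scale — not robustness of the original
field inferences to heterogeneity or spatial effects.

## Verification design and problem sizes

Recovery tests run at the study scale: ~3,000 marked adults, 42
occasions. Single fits of constant, sex- and season-structured models
check estimates against generating truth within 3 reported SEs.
Covariate-slope studies average 100 replicates and check the mean
against truth within Monte-Carlo error. POPAN recovery uses 200
replicates of a superpopulation of 2,000 over 8 occasions (mean relative
bias of abundance under 5%); AICc selection power uses 50 replicates of
a 20-occasion seasonal design. These sizes keep the whole suite and the
acceptance script within a few minutes on one CPU while leaving
Monte-Carlo error well below the tolerances they check.

One measured subtlety: under the declining overall rates
(λ_m = 0.964, populations shrink ~6× over the study and approach
extinction late), the replicate-mean of the growth estimate sits about
5e−4 below the generating value. The shortfall does not shrink with
population size but vanishes exactly for stationary configurations, so
it is a property of fitting a deterministic-growth model to stochastic
trajectories near extinction, not an estimator defect; the tests assert
survival/recruitment unbiasedness at 2 MC SE, the exact identity
λ = φ + f, and bound the growth shortfall at 0.002.

## Known limitations

- No overdispersion (ĉ) adjustment, bootstrap GOF, or multi-state /
  robust-design structure.
- Formula vocabulary is fixed (no splines, no individual covariates).
- FD-gradient optimization is adequate up to K ≈ 100; larger designs
  would want analytic gradients.
- The sampling-area covariate is a single switch at October 1997;
  grid-level spatial variation is out of scope.
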