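"""POPAN (Jolly-Seber superpopulation) abundance estimation.

The superpopulation N_super is every animal ever present during the study;
entry proportions pent_1..pent_T (summing to one, multinomial-logit
internally) allocate it to arrival occasions.  Occasion abundance follows
the recursion psi_1 = pent_1, psi_{t+1} = psi_t Phi_t + pent_{t+1},
N_t = N_super psi_t.

The full likelihood combines a binomial term for observing n distinct
animals out of N_super — with Pr(never detected) from the entry-weighted
never-seen recursion nu_t = (1 - p_t)[(1 - Phi_t) + Phi_t nu_{t+1}] —
with multinomial history terms mixing over unobserved entry occasions.
Survival is modelled on the monthly scale and scaled by interval length,
as in the Pradel engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln
from statsmodels.tools import numdiff

from .calendar import OccasionCalendar
from .design import compile_parameter_design
from .histories import CaptureHistorySet
from .likelihood import inverse_link, link_fn

_EPS = 1e-12
_BIG = 1e10


def _softmax_pent(free: np.ndarray, T: int) -> np.ndarray:
    z = np.concatenate([[0.0], np.asarray(free, dtype=float)])
    z = z - z.max()
    w = np.exp(z)
    return w / w.sum()


def popan_negloglik(
    chs: CaptureHistorySet,
    p: np.ndarray,
    Phi: np.ndarray,
    pent: np.ndarray,
    n_super: float,
) -> float:
    """Full POPAN negative log-likelihood at interval-scale parameters.

    ``p`` per occasion, ``Phi`` per interval (already Delta-t scaled),
    ``pent`` per occasion summing to 1, ``n_super`` the (continuous)
    superpopulation size.  Constant multinomial coefficients over observed
    pattern counts are dropped.
    """
    T = chs.n_occasions
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1 - _EPS)
    Phi = np.clip(np.asarray(Phi, dtype=float), _EPS, 1 - _EPS)
    pent = np.asarray(pent, dtype=float)
    if abs(pent.sum() - 1) > 1e-8 or (pent < 0).any():
        raise ValueError("pent must be a probability vector over occasions")
    n = chs.total_individuals()
    if n_super < n:
        return _BIG

    # never-detected probability given entry at each occasion
    nu = np.empty(T)
    nu[T - 1] = 1 - p[T - 1]
    for t in range(T - 2, -1, -1):
        nu[t] = (1 - p[t]) * ((1 - Phi[t]) + Phi[t] * nu[t + 1])
    pr_never = float(np.dot(pent, nu))

    # omega_a: Pr(enter at e <= a, survive to a, undetected before a)
    omega = np.empty(T)
    omega[0] = pent[0]
    for t in range(T - 1):
        omega[t + 1] = pent[t + 1] + omega[t] * (1 - p[t]) * Phi[t]

    # chi_b: never detected after b given alive at b
    chi = np.ones(T)
    for t in range(T - 2, -1, -1):
        chi[t] = (1 - Phi[t]) + Phi[t] * (1 - p[t + 1]) * chi[t + 1]

    H = chs.histories
    counts = chs.counts.sum(axis=1).astype(float)
    idx = np.arange(T)
    first = np.argmax(H, axis=1)
    last = T - 1 - np.argmax(H[:, ::-1], axis=1)
    logp = np.log(p)
    log1mp = np.log(1 - p)
    logPhi = np.log(Phi)
    csPhi = np.concatenate([[0.0], np.cumsum(logPhi)])
    core_mask = (idx[None, :] > first[:, None]) & (idx[None, :] <= last[:, None])
    det_terms = np.where(H == 1, logp[None, :], log1mp[None, :])
    core = (core_mask * det_terms).sum(axis=1)
    loglik_h = (
        np.log(np.maximum(omega[first], 1e-300))
        + logp[first]
        + csPhi[last]
        - csPhi[first]
        + core
        + np.log(np.maximum(chi[last], 1e-300))
    )

    ll = (
        gammaln(n_super + 1)
        - gammaln(n_super - n + 1)
        + (n_super - n) * np.log(max(pr_never, 1e-300))
        + float(np.dot(counts, loglik_h))
    )
    if not np.isfinite(ll):
        return _BIG
    return -float(ll)


@dataclass
class PopanModel:
    """Fitted POPAN model with derived abundance series."""

    chs: CaptureHistorySet
    calendar: OccasionCalendar
    p_formula: str
    phi_formula: str
    theta: np.ndarray
    vcov: np.ndarray | None
    nll: float
    k: int
    converged: bool
    n_starts_used: int
    p: np.ndarray = field(default=None)
    Phi: np.ndarray = field(default=None)
    pent: np.ndarray = field(default=None)
    n_super: float = 0.0
    abundance: pd.DataFrame | None = None


class _PopanCompiled:
    def __init__(self, chs, p_formula, phi_formula, covariates=None):
        if chs.calendar is None:
            raise ValueError("history set must carry a calendar")
        self.chs = chs.pool_groups()
        cal = chs.calendar
        self.calendar = cal
        self.T = cal.n_occasions
        self.dt = cal.interval_months
        self.Xp = compile_parameter_design("p", p_formula, cal, ["all"], covariates)
        self.Xphi = compile_parameter_design("phi", phi_formula, cal, ["all"], covariates)
        self.n = self.chs.total_individuals()
        self.kp = self.Xp.k
        self.kphi = self.Xphi.k
        self.k = self.kp + self.kphi + (self.T - 1) + 1

    def unpack(self, theta):
        kp, kphi, T = self.kp, self.kphi, self.T
        bp = theta[:kp]
        bphi = theta[kp : kp + kphi]
        free = theta[kp + kphi : kp + kphi + T - 1]
        log_extra = theta[-1]
        p = inverse_link(self.Xp.X @ bp, "logit")
        phi_m = inverse_link(self.Xphi.X @ bphi, "logit")
        Phi = phi_m[: self.T - 1] ** self.dt
        pent = _softmax_pent(free, T)
        n_super = self.n + np.exp(np.clip(log_extra, -700, 700))
        return p, Phi, pent, n_super

    def nll(self, theta):
        try:
            p, Phi, pent, n_super = self.unpack(np.asarray(theta, dtype=float))
        except (ValueError, FloatingPointError):
            return _BIG
        return popan_negloglik(self.chs, p, Phi, pent, n_super)

    def abundance_series(self, theta):
        p, Phi, pent, n_super = self.unpack(np.asarray(theta, dtype=float))
        psi = np.empty(self.T)
        psi[0] = pent[0]
        for t in range(self.T - 1):
            psi[t + 1] = psi[t] * Phi[t] + pent[t + 1]
        return n_super * psi


def fit_popan(
    chs: CaptureHistorySet,
    p_formula: str = "~1",
    phi_formula: str = "~1",
    covariates: pd.DataFrame | None = None,
    starts: int = 3,
    seed: int = 0,
    compute_vcov: bool = True,
    maxiter: int = 2000,
) -> PopanModel:
    """Fit POPAN by maximum likelihood; entry proportions are always
    occasion-specific (multinomial logit), survival and capture follow the
    given formulas on monthly/logit scales.

    Returns the fitted model with an occasion-by-occasion abundance series
    N_t = N_super psi_t and delta-method SEs.
    """
    comp = _PopanCompiled(chs, p_formula, phi_formula, covariates)
    rng = np.random.default_rng(seed)
    theta0 = np.zeros(comp.k)
    theta0[-1] = np.log(max(comp.n, 2.0))  # start N_super near 2n
    best = None
    n_used = 0
    for s in range(max(1, starts)):
        x0 = theta0 if s == 0 else theta0 + rng.normal(0, 0.5, comp.k)
        try:
            res = optimize.minimize(
                comp.nll,
                x0,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "maxfun": 10**7,
                         "ftol": 1e-11, "gtol": 1e-7},
            )
        except Exception:  # pragma: no cover
            continue
        n_used += 1
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-9):
            best = res
    if best is None:
        raise RuntimeError("all POPAN starts failed")

    theta = best.x
    p, Phi, pent, n_super = comp.unpack(theta)
    vcov = None
    se_N = np.full(comp.T, np.nan)
    if compute_vcov:
        try:
            hess = numdiff.approx_hess1(theta, comp.nll)
            hess = 0.5 * (hess + hess.T)
            vcov = np.linalg.pinv(hess)
            J = numdiff.approx_fprime(theta, comp.abundance_series)
            cov_N = J @ vcov @ J.T
            se_N = np.sqrt(np.maximum(np.diag(cov_N), 0.0))
        except Exception:  # pragma: no cover
            pass

    N = comp.abundance_series(theta)
    abundance = pd.DataFrame(
        {
            "occasion": np.arange(1, comp.T + 1),
            "date": [str(d) for d in comp.calendar.dates],
            "N": N,
            "SE": se_N,
        }
    )
    nll = float(best.fun)
    grad_norm = float(np.max(np.abs(best.jac)))
    return PopanModel(
        chs=comp.chs,
        calendar=comp.calendar,
        p_formula=p_formula,
        phi_formula=phi_formula,
        theta=theta,
        vcov=vcov,
        nll=nll,
        k=comp.k,
        converged=bool(best.success) and grad_norm <= 1e-4 * max(1.0, abs(nll)),
        n_starts_used=n_used,
        p=p,
        Phi=Phi,
        pent=pent,
        n_super=float(n_super),
        abundance=abundance,
    )
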