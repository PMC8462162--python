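"""Pradel temporal-symmetry likelihood with unequal interval lengths.

The model views a history both forward and backward in time.  Forward,
an animal alive at occasion t survives interval t with probability Phi_t
and, if alive at t+1, is detected with probability p_{t+1}.  Backward, an
animal present at occasion t+1 was already present at t with seniority
probability gamma_{t+1}; population growth over the interval is
Lambda_t = Phi_t / gamma_{t+1}, and recruitment per capita is
F_t = Lambda_t - Phi_t.

All vital rates are modelled on the monthly scale and raised to the
interval length in months (Delta t in {5, 7} for the biannual design):
Phi_t = phi_m^{dt}, Lambda_t = lambda_m^{dt}, hence
gamma_{t+1} = (phi_m / lambda_m)^{dt}.

The likelihood is conditional on an animal being captured at least once.
With r_t the abundance at t relative to occasion 1 (products of Lambda),
xi_t the probability an animal present at t was never detected before t,
and chi_t the probability an animal alive at t is never detected after t,
a history first seen at a and last seen at b has conditional probability

    r_a xi_a p_a [prod_{t=a}^{b-1} Phi_t p_{t+1}^{y} (1-p_{t+1})^{1-y}]
        chi_b / C,        C = sum_t r_t xi_t p_t.
"""

from __future__ import annotations

import numpy as np

from .design import ParamDesign, PradelModelSpec, compile_design, total_k
from .histories import CaptureHistorySet

_P_FLOOR = 1e-300
_EPS = 1e-12


def _check_prob(x, name):
    x = np.asarray(x, dtype=float)
    if ((x < 0) | (x > 1) | ~np.isfinite(x)).any():
        raise ValueError(f"{name} must lie in [0,1]")
    return x


def chi_recursion(Phi, p) -> np.ndarray:
    """chi_t: Pr(never detected after t | alive at t), t = 1..T.

    ``Phi`` has length T-1 (interval scale), ``p`` length T (p[0] unused).
    chi_T = 1; chi_t = (1 - Phi_t) + Phi_t (1 - p_{t+1}) chi_{t+1}.
    """
    Phi = _check_prob(Phi, "Phi")
    p = _check_prob(p, "p")
    T = len(p)
    if len(Phi) != T - 1:
        raise ValueError("Phi must have length T-1")
    chi = np.ones(T)
    for t in range(T - 2, -1, -1):
        chi[t] = (1 - Phi[t]) + Phi[t] * (1 - p[t + 1]) * chi[t + 1]
    return chi


def xi_recursion(gamma, p) -> np.ndarray:
    """xi_t: Pr(never detected before t | present at t), t = 1..T.

    ``gamma`` has length T-1 (gamma[t-1] is the seniority of occasion t+1,
    1-based), ``p`` length T (p[T-1] unused).  The reverse-time mirror of
    :func:`chi_recursion`:
    xi_1 = 1; xi_t = (1 - gamma_t) + gamma_t (1 - p_{t-1}) xi_{t-1}.
    """
    gamma = _check_prob(gamma, "gamma")
    p = _check_prob(p, "p")
    T = len(p)
    if len(gamma) != T - 1:
        raise ValueError("gamma must have length T-1")
    xi = np.ones(T)
    for t in range(1, T):
        xi[t] = (1 - gamma[t - 1]) + gamma[t - 1] * (1 - p[t - 1]) * xi[t - 1]
    return xi


def relative_abundance(Lambda) -> np.ndarray:
    """r_t: expected abundance at t relative to occasion 1 (r_1 = 1)."""
    Lambda = np.asarray(Lambda, dtype=float)
    if (Lambda <= 0).any():
        raise ValueError("Lambda must be positive")
    return np.concatenate([[1.0], np.cumprod(Lambda)])


def cell_log_probabilities(
    histories: np.ndarray, p, Phi, gamma
) -> np.ndarray:
    """Log conditional probability of each history pattern (vectorized).

    Parameters are on the interval scale; ``gamma[i]`` is the seniority of
    occasion i+2 (1-based gamma_{t+1} for interval i).
    """
    H = np.atleast_2d(np.asarray(histories, dtype=np.int8))
    p = _check_prob(p, "p")
    Phi = _check_prob(Phi, "Phi")
    gamma = _check_prob(gamma, "gamma")
    T = H.shape[1]
    if (H.sum(axis=1) == 0).any():
        raise ValueError("all-zero history has no conditional probability")
    if (gamma == 0).any():
        raise ValueError("gamma must be positive (Lambda = Phi/gamma)")
    Lambda = Phi / gamma
    r = relative_abundance(Lambda)
    xi = xi_recursion(gamma, p)
    chi = chi_recursion(Phi, p)
    C = float(np.sum(r * xi * p))

    logp = np.log(np.maximum(p, _P_FLOOR))
    log1mp = np.log(np.maximum(1 - p, _P_FLOOR))
    logPhi = np.log(np.maximum(Phi, _P_FLOOR))
    csPhi = np.concatenate([[0.0], np.cumsum(logPhi)])  # csPhi[t] = sum logPhi[:t]

    idx = np.arange(T)
    first = np.argmax(H, axis=1)
    last = T - 1 - np.argmax(H[:, ::-1], axis=1)

    core_mask = (idx[None, :] > first[:, None]) & (idx[None, :] <= last[:, None])
    det_terms = np.where(H == 1, logp[None, :], log1mp[None, :])
    core = (core_mask * det_terms).sum(axis=1)
    surv = csPhi[last] - csPhi[first]

    return (
        np.log(np.maximum(r[first], _P_FLOOR))
        + np.log(np.maximum(xi[first], _P_FLOOR))
        + logp[first]
        + surv
        + core
        + np.log(np.maximum(chi[last], _P_FLOOR))
        - np.log(C)
    )


def cell_probability(history, p, Phi, gamma) -> float:
    """Conditional probability of a single history (convenience wrapper)."""
    return float(np.exp(cell_log_probabilities(np.asarray(history)[None, :], p, Phi, gamma))[0])


def enumerate_observable_histories(T: int) -> np.ndarray:
    """All 2^T - 1 histories with at least one detection (oracle helper)."""
    n = 2**T
    bits = ((np.arange(1, n)[:, None] >> np.arange(T - 1, -1, -1)) & 1).astype(np.int8)
    return bits


# ---------------------------------------------------------------------------
# Parameterization maps (monthly <-> interval scales)
# ---------------------------------------------------------------------------


def map_parameterizations(
    dt,
    phi_m,
    f_m=None,
    lambda_m=None,
    gamma_m=None,
) -> dict:
    """Complete the monthly and interval-scale parameter sets.

    Give exactly one of ``f_m``, ``lambda_m`` or ``gamma_m`` alongside
    ``phi_m`` (all per interval, broadcastable against ``dt``):

    - lambda_m = phi_m + f_m,
    - Phi_t = phi_m^{dt}, Lambda_t = lambda_m^{dt},
    - gamma_{t+1} = Phi_t / Lambda_t = gamma_m^{dt}  with gamma_m = phi_m/lambda_m,
    - F_t = Lambda_t - Phi_t  (interval-scale recruitment).
    """
    dt = np.asarray(dt, dtype=float)
    phi_m = np.broadcast_to(np.asarray(phi_m, dtype=float), dt.shape).copy()
    given = [v is not None for v in (f_m, lambda_m, gamma_m)]
    if sum(given) != 1:
        raise ValueError("give exactly one of f_m, lambda_m, gamma_m")
    if f_m is not None:
        f_m = np.broadcast_to(np.asarray(f_m, dtype=float), dt.shape).copy()
        if (f_m < 0).any():
            raise ValueError("monthly recruitment must be nonnegative")
        lambda_m = phi_m + f_m
    elif lambda_m is not None:
        lambda_m = np.broadcast_to(np.asarray(lambda_m, dtype=float), dt.shape).copy()
        f_m = lambda_m - phi_m
    else:
        gamma_m = np.broadcast_to(np.asarray(gamma_m, dtype=float), dt.shape).copy()
        if ((gamma_m <= 0) | (gamma_m > 1)).any():
            raise ValueError("monthly seniority must lie in (0,1]")
        lambda_m = phi_m / gamma_m
        f_m = lambda_m - phi_m
    if (lambda_m <= 0).any():
        raise ValueError("monthly growth rate must be positive")
    gamma_m = phi_m / lambda_m
    out = {
        "phi_m": phi_m,
        "f_m": f_m,
        "lambda_m": lambda_m,
        "gamma_m": gamma_m,
        "Phi": phi_m**dt,
        "Lambda": lambda_m**dt,
        "gamma": gamma_m**dt,
        "dt": dt,
    }
    out["F"] = out["Lambda"] - out["Phi"]
    if (out["gamma"] > 1 + _EPS).any():
        out["negative_recruitment_flag"] = True
    return out


# ---------------------------------------------------------------------------
# Link functions
# ---------------------------------------------------------------------------


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))


def inverse_link(eta, link):
    if link == "logit":
        return _expit(eta)
    if link == "log":
        return np.exp(np.clip(eta, -700, 700))
    raise ValueError(f"unknown link {link!r}")


def inverse_link_deriv(eta, link):
    if link == "logit":
        mu = _expit(eta)
        return mu * (1 - mu)
    if link == "log":
        return np.exp(np.clip(eta, -700, 700))
    raise ValueError(f"unknown link {link!r}")


def link_fn(mu, link):
    mu = np.asarray(mu, dtype=float)
    if link == "logit":
        return np.log(mu / (1 - mu))
    if link == "log":
        return np.log(mu)
    raise ValueError(f"unknown link {link!r}")


# ---------------------------------------------------------------------------
# Compiled model: designs + data, evaluating the NLL
# ---------------------------------------------------------------------------


class CompiledPradelModel:
    """A model spec compiled against a data set, ready for NLL evaluation.

    Slices one concatenated link-scale coefficient vector beta into the
    per-parameter designs, maps monthly rates to interval scale through the
    calendar's Delta t, and sums the pattern log-likelihood per sex group.
    """

    def __init__(
        self,
        chs: CaptureHistorySet,
        spec: PradelModelSpec,
        covariates=None,
    ):
        if chs.calendar is None:
            raise ValueError("history set must carry an occasion calendar")
        uses_sex = any("sex" in spec.formula(p) for p in spec.param_names)
        if uses_sex and "unknown" in chs.groups:
            chs = chs.select_groups([g for g in chs.groups if g != "unknown"])
        self.chs = chs
        self.spec = spec
        self.calendar = chs.calendar
        self.dt = self.calendar.interval_months
        self.designs: dict[str, ParamDesign] = compile_design(
            spec, self.calendar, chs.groups, covariates
        )
        self.k = total_k(self.designs)
        self._slices = {}
        off = 0
        for param in spec.param_names:
            k = self.designs[param].k
            self._slices[param] = slice(off, off + k)
            off += k
        # per-group pattern matrices with nonzero counts
        self._group_patterns = []
        for gi, g in enumerate(chs.groups):
            nz = chs.counts[:, gi] > 0
            self._group_patterns.append(
                (chs.histories[nz], chs.counts[nz, gi].astype(float))
            )
        self.negative_recruitment_flag = False

    @property
    def beta_names(self) -> list[str]:
        names = []
        for param in self.spec.param_names:
            names.extend(f"{param}:{c}" for c in self.designs[param].colnames)
        return names

    def split(self, beta) -> dict[str, np.ndarray]:
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.k,):
            raise ValueError(f"beta must have length {self.k}")
        return {p: beta[s] for p, s in self._slices.items()}

    def group_rates(self, beta) -> list[dict]:
        """Real-scale parameters per group: p (occasion), monthly + interval rates."""
        parts = self.split(beta)
        sec = self.spec.second
        out = []
        for gi in range(len(self.chs.groups)):
            eta_p = self.designs["p"].group_block(gi) @ parts["p"]
            eta_phi = self.designs["phi"].group_block(gi) @ parts["phi"]
            eta_sec = self.designs[sec].group_block(gi) @ parts[sec]
            p = inverse_link(eta_p, "logit")
            phi_m = inverse_link(eta_phi, "logit")
            kw = {("f_m" if sec == "f" else "lambda_m" if sec == "lambda" else "gamma_m"):
                  inverse_link(eta_sec, LINK_BY_PARAM[sec])}
            rates = map_parameterizations(self.dt, phi_m, **kw)
            rates["p"] = p
            out.append(rates)
        return out

    def nll(self, beta) -> float:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._nll(beta)

    def _nll(self, beta) -> float:
        try:
            per_group = self.group_rates(beta)
        except (ValueError, FloatingPointError):
            return 1e10
        total = 0.0
        for (patterns, counts), rates in zip(self._group_patterns, per_group):
            if rates.get("negative_recruitment_flag"):
                self.negative_recruitment_flag = True
            p = np.clip(rates["p"], _EPS, 1 - _EPS)
            Phi = np.clip(rates["Phi"], _EPS, 1 - _EPS)
            gamma = np.clip(rates["gamma"], _EPS, 1 - _EPS)
            if len(patterns) == 0:
                continue
            ll = cell_log_probabilities(patterns, p, Phi, gamma)
            total -= float(np.dot(counts, ll))
        if not np.isfinite(total):
            return 1e10
        return total


LINK_BY_PARAM = {"p": "logit", "phi": "logit", "f": "log", "lambda": "log",
                 "gamma": "logit"}


def negloglik(
    chs: CaptureHistorySet,
    spec: PradelModelSpec,
    beta,
    covariates=None,
) -> float:
    """Negative log-likelihood of ``beta`` for ``spec`` on ``chs``."""
    return CompiledPradelModel(chs, spec, covariates).nll(beta)
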