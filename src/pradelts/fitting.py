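"""Maximum-likelihood fitting, AICc model tables and derived summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools import numdiff

from .design import LINKS
from .histories import CaptureHistorySet
from .likelihood import (
    CompiledPradelModel,
    PradelModelSpec,
    inverse_link,
    inverse_link_deriv,
    link_fn,
)

log = logging.getLogger(__name__)

#: link-scale starting values for intercept-like columns
_INIT = {"p": 0.0, "phi": 0.0, "f": np.log(0.15), "lambda": 0.0,
         "gamma": float(link_fn(0.8, "logit"))}

_Z95 = 1.959963984540054


def effective_sample_size(chs: CaptureHistorySet, kind: str = "detections") -> int:
    """AICc sample-size surrogate: total detections (default) or individuals."""
    if kind == "detections":
        return chs.total_detections()
    if kind == "individuals":
        return chs.total_individuals()
    raise ValueError(f"unknown ESS kind {kind!r}")


def aicc(nll: float, k: int, ess: float) -> float:
    """Small-sample corrected AIC: 2 nll + 2K + 2K(K+1)/(ess - K - 1)."""
    if ess <= k + 1:
        raise ValueError(f"ESS {ess} must exceed K+1 = {k + 1}")
    return 2.0 * nll + 2.0 * k + 2.0 * k * (k + 1) / (ess - k - 1)


@dataclass
class FittedModel:
    spec: PradelModelSpec
    model: CompiledPradelModel
    beta: np.ndarray
    vcov: np.ndarray | None
    nll: float
    k: int
    ess: int
    aicc: float
    converged: bool
    n_starts_used: int
    grad_norm: float
    estimable: int
    flags: dict = field(default_factory=dict)

    @property
    def beta_names(self) -> list[str]:
        return self.model.beta_names

    def beta_se(self) -> np.ndarray:
        if self.vcov is None:
            return np.full(self.k, np.nan)
        return np.sqrt(np.maximum(np.diag(self.vcov), 0.0))

    def name(self) -> str:
        return self.spec.name()


def _start_vector(model: CompiledPradelModel) -> np.ndarray:
    beta0 = np.zeros(model.k)
    for param, sl in model._slices.items():
        names = model.designs[param].colnames
        init = _INIT[param]
        vals = np.zeros(len(names))
        for j, nm in enumerate(names):
            if nm == "(Intercept)" or nm.startswith(("time[", "year[")) and ":" not in nm:
                vals[j] = init
        beta0[sl] = vals
    return beta0


def fit(
    chs: CaptureHistorySet,
    spec: PradelModelSpec,
    covariates: pd.DataFrame | None = None,
    starts: int = 5,
    seed: int = 0,
    jitter_sd: float = 0.5,
    ess_kind: str = "detections",
    compute_vcov: bool = True,
    maxiter: int = 1000,
) -> FittedModel:
    """Maximize the Pradel likelihood from multiple jittered starts.

    Quasi-Newton (L-BFGS-B) on the link scale; the first start uses the
    canonical initial point (probability intercepts at 0.5, recruitment at
    0.15, slopes at 0), subsequent starts add N(0, jitter_sd^2) noise.
    The best optimum across starts is retained; the covariance of the MLEs
    is the inverse observed-information (numerical Hessian).
    """
    model = CompiledPradelModel(chs, spec, covariates)
    rng = np.random.default_rng(seed)
    beta0 = _start_vector(model)
    best = None
    n_used = 0
    for s in range(max(1, starts)):
        x0 = beta0 if s == 0 else beta0 + rng.normal(0.0, jitter_sd, model.k)
        try:
            res = optimize.minimize(
                model.nll,
                x0,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "maxfun": 10**7,
                         "ftol": 1e-11, "gtol": 1e-6},
            )
        except Exception as exc:  # pragma: no cover - optimizer pathologies
            log.warning("start %d failed: %s", s, exc)
            continue
        n_used += 1
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-9):
            best = res
    if best is None:
        raise RuntimeError("all optimization starts failed")

    beta_hat = best.x
    nll = float(best.fun)
    grad = np.asarray(best.jac, dtype=float)
    grad_norm = float(np.max(np.abs(grad)))
    # finite-difference gradient noise scales with |NLL| (roundoff |f|*eps/h
    # is O(0.1) at |NLL| ~ 1e4), so convergence is judged relative to the
    # objective rather than against an absolute gradient norm
    converged = bool(best.success) and grad_norm <= 1e-4 * max(1.0, abs(nll))

    vcov = None
    estimable = model.k
    flags: dict = {}
    if model.negative_recruitment_flag:
        flags["negative_implied_recruitment"] = True
    if compute_vcov:
        try:
            hess = numdiff.approx_hess1(beta_hat, model.nll)
            hess = 0.5 * (hess + hess.T)
            eigvals = np.linalg.eigvalsh(hess)
            tol = max(1e-8, 1e-10 * max(eigvals.max(), 1.0))
            estimable = int((eigvals > tol).sum())
            if estimable < model.k:
                flags["singular_hessian"] = True
                vcov = np.linalg.pinv(hess)
            else:
                vcov = np.linalg.inv(hess)
            d = np.diag(vcov)
            if (d < -1e-8).any():
                flags["nonpositive_variance"] = True
                vcov = np.linalg.pinv(hess)
        except Exception as exc:  # pragma: no cover
            log.warning("Hessian failed: %s", exc)
            flags["vcov_failed"] = True

    ess = effective_sample_size(chs, ess_kind)
    return FittedModel(
        spec=spec,
        model=model,
        beta=beta_hat,
        vcov=vcov,
        nll=nll,
        k=model.k,
        ess=ess,
        aicc=aicc(nll, model.k, ess),
        converged=converged,
        n_starts_used=n_used,
        grad_norm=grad_norm,
        estimable=estimable,
        flags=flags,
    )


def model_table(fits: dict[str, FittedModel] | list[FittedModel]) -> pd.DataFrame:
    """AICc ranking with Akaike weights (best model at Delta AICc = 0)."""
    if isinstance(fits, dict):
        items = list(fits.items())
    else:
        items = [(f.name(), f) for f in fits]
    if not items:
        raise ValueError("no fitted models")
    df = pd.DataFrame(
        {
            "model": [n for n, _ in items],
            "K": [f.k for _, f in items],
            "AICc": [f.aicc for _, f in items],
            "converged": [f.converged for _, f in items],
        }
    )
    df["dAICc"] = df["AICc"] - df["AICc"].min()
    w = np.exp(-0.5 * df["dAICc"].to_numpy())
    df["weight"] = w / w.sum()
    return df.sort_values("AICc", ignore_index=True)


def real_estimates(fitted: FittedModel, omit_first_lambda: bool = True) -> pd.DataFrame:
    """Real-scale (monthly) estimates with delta-method SEs and 95% CIs.

    CIs are computed on the link scale and back-transformed, so they stay
    inside each parameter's admissible range.  For time-specific models the
    first realized-growth estimate is omitted (it is confounded with entry
    in temporal-symmetry models); set ``omit_first_lambda=False`` to keep it.
    """
    model = fitted.model
    parts = model.split(fitted.beta)
    rows = []
    for param in model.spec.param_names:
        des = model.designs[param]
        link = LINKS[param]
        V = None
        if fitted.vcov is not None:
            sl = model._slices[param]
            V = fitted.vcov[sl, sl]
        for gi, g in enumerate(model.chs.groups):
            X = des.group_block(gi)
            eta = X @ parts[param]
            se_eta = (
                np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, V, X), 0.0))
                if V is not None
                else np.full(len(eta), np.nan)
            )
            est = inverse_link(eta, link)
            se = np.abs(inverse_link_deriv(eta, link)) * se_eta
            lcl = inverse_link(eta - _Z95 * se_eta, link)
            ucl = inverse_link(eta + _Z95 * se_eta, link)
            if link == "logit":
                inest = ((lcl < 0.001) & (ucl > 0.999)) | (se_eta > 10)
            else:
                inest = se_eta > 10
            for i in range(len(eta)):
                rows.append(
                    {
                        "parameter": param,
                        "group": g,
                        "index": i + 1,
                        "estimate": est[i],
                        "se": se[i],
                        "lcl": lcl[i],
                        "ucl": ucl[i],
                        "inestimable": bool(inest[i]) if V is not None else True,
                    }
                )
    df = pd.DataFrame(rows)
    if omit_first_lambda and "time" in fitted.spec.formula("lambda") and (
        fitted.spec.second == "lambda"
    ):
        df = df[~((df["parameter"] == "lambda") & (df["index"] == 1))]
    return df.reset_index(drop=True)


def covariate_effect(
    fitted: FittedModel, covariate: str, param: str | None = None
) -> dict:
    """Slope estimate, SE, 95% CI and CI-based significance for a covariate."""
    names = fitted.beta_names
    matches = [
        i
        for i, nm in enumerate(names)
        if nm.split(":", 1)[1] == covariate
        and (param is None or nm.startswith(param + ":"))
    ]
    if not matches:
        raise KeyError(f"covariate {covariate!r} not in fitted design")
    if len(matches) > 1:
        raise KeyError(
            f"covariate {covariate!r} ambiguous across parameters; pass param="
        )
    i = matches[0]
    beta = float(fitted.beta[i])
    se = float(fitted.beta_se()[i])
    lcl, ucl = beta - _Z95 * se, beta + _Z95 * se
    return {
        "covariate": covariate,
        "parameter": names[i].split(":", 1)[0],
        "beta": beta,
        "se": se,
        "lcl": lcl,
        "ucl": ucl,
        "significant": bool(lcl > 0 or ucl < 0),
    }


@dataclass
class SeniorityResult:
    gamma: np.ndarray  # interval-scale seniority series Phi_t / Lambda_t
    gamma_monthly: np.ndarray  # monthly-scale phi_m / lambda_m per interval
    mean: float  # of the monthly series (the reporting convention here)
    sd: float
    range: tuple[float, float]
    mean_interval: float
    survival_dominated: np.ndarray  # monthly gamma > 0.5 per interval
    n_excluded: int


def seniority_summary(
    fitted: FittedModel, group: int = 0, exclude: list[int] | None = None
) -> SeniorityResult:
    """Seniority gamma_{t+1} = Phi_t / Lambda_t and its summary.

    The monthly-scale seniority gamma_m = phi_m / lambda_m is the headline
    series (the proportion of animals present in a month that survived from
    the previous month); gamma_m > 0.5 marks periods where survival
    contributes more to realized growth than recruitment.  The interval-scale
    series (gamma_m^{dt}) is also returned.  ``exclude`` lists 1-based
    intervals to drop (e.g. those with inestimable growth).
    """
    rates = fitted.model.group_rates(fitted.beta)[group]
    gamma = np.asarray(rates["gamma"], dtype=float)
    gamma_m = np.asarray(rates["gamma_m"], dtype=float)
    mask = np.ones(len(gamma), dtype=bool)
    n_excluded = 0
    if exclude:
        for t in exclude:
            mask[t - 1] = False
        n_excluded = int((~mask).sum())
    g = gamma_m[mask]
    return SeniorityResult(
        gamma=gamma,
        gamma_monthly=gamma_m,
        mean=float(g.mean()),
        sd=float(g.std(ddof=1)) if len(g) > 1 else 0.0,
        range=(float(g.min()), float(g.max())),
        mean_interval=float(gamma[mask].mean()),
        survival_dominated=gamma_m > 0.5,
        n_excluded=n_excluded,
    )


def correlate_series(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-D series with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
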