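"""Formula-based design matrices on link scales.

Each model parameter (p, phi, f / lambda / gamma) carries a small Wilkinson
formula over a fixed vocabulary: ``1`` (intercept), ``time``, ``year``,
``season``, ``sex``, ``area`` and any numeric per-interval covariate by
name, composed additively (``+``) or with interaction expansion (``*``,
meaning main effects plus the product term).  ``p`` is indexed by occasion,
the vital rates by interval.

Encoding rules follow MARK's conventions for these model names: a ``time``
(or ``year``) term absorbs the intercept and gets one column per level,
every other factor is treatment-coded against a reference level, so e.g. on
a 42-occasion calendar phi(~time) has 41 columns, p(~season + sex) has 3
and p(~season * sex) has 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calendar import OccasionCalendar

PARAMETERIZATIONS = ("phi_f", "phi_lambda", "phi_gamma")

#: second parameter of each parameterization and its link
SECOND_PARAM = {"phi_f": "f", "phi_lambda": "lambda", "phi_gamma": "gamma"}

LINKS = {"p": "logit", "phi": "logit", "gamma": "logit", "f": "log", "lambda": "log"}

_FULL_RANK_FACTORS = ("time", "year")
_FACTORS = ("time", "year", "season", "sex")


@dataclass(frozen=True)
class PradelModelSpec:
    """Parameterization plus one formula per parameter.

    ``formulas`` maps ``"p"``, ``"phi"`` and the second parameter
    (``"f"``, ``"lambda"`` or ``"gamma"``) to formula strings like
    ``"~season + sex"``.  Missing entries default to ``"~1"``.
    """

    parameterization: str = "phi_f"
    formulas: dict = field(default_factory=dict)
    standardize_covariates: bool = True

    def __post_init__(self):
        if self.parameterization not in PARAMETERIZATIONS:
            raise ValueError(f"unknown parameterization {self.parameterization!r}")
        second = SECOND_PARAM[self.parameterization]
        for key in self.formulas:
            if key not in ("p", "phi", second):
                raise ValueError(
                    f"formula for {key!r} not valid under {self.parameterization}"
                )

    @property
    def second(self) -> str:
        return SECOND_PARAM[self.parameterization]

    @property
    def param_names(self) -> tuple[str, str, str]:
        return ("phi", self.second, "p")

    def formula(self, param: str) -> str:
        return self.formulas.get(param, "~1")

    def name(self) -> str:
        phi, sec, p = self.param_names
        return (
            f"phi({self.formula('phi')}) p({self.formula('p')}) "
            f"{sec}({self.formula(sec)})"
        )

    def with_formula(self, param: str, formula: str) -> "PradelModelSpec":
        f = dict(self.formulas)
        f[param] = formula
        return replace(self, formulas=f)


def parse_formula(formula: str) -> list[tuple[str, ...]]:
    """Expand a formula string into a list of terms (tuples of factor names).

    ``"~a + b"`` -> [(a,), (b,)]; ``"~a * b"`` -> [(a,), (b,), (a, b)].
    ``"~1"`` -> [].
    """
    body = formula.strip().lstrip("~").strip()
    if body in ("", "1"):
        return []
    terms: list[tuple[str, ...]] = []
    for chunk in body.split("+"):
        chunk = chunk.strip()
        if not chunk or chunk == "1":
            continue
        if "*" in chunk:
            parts = [p.strip() for p in chunk.split("*")]
            for p in parts:
                if (p,) not in terms:
                    terms.append((p,))
            terms.append(tuple(parts))
        elif ":" in chunk:
            terms.append(tuple(p.strip() for p in chunk.split(":")))
        else:
            terms.append((chunk,))
    return terms


def _feature_frame(
    calendar: OccasionCalendar,
    level: str,
    groups: list[str],
    covariates: pd.DataFrame | None,
) -> pd.DataFrame:
    """Long feature frame: one row per (group, occasion-or-interval)."""
    if level == "occasion":
        n = calendar.n_occasions
        base = pd.DataFrame(
            {
                "time": np.arange(1, n + 1),
                "season": calendar.occasion_seasons,
                "year": calendar.occasion_years(),
                "area": calendar.area_indicator()
                if calendar.dates[0] <= pd.Period("1997-10") <= calendar.dates[-1]
                else np.zeros(n),
            }
        )
    else:
        n = calendar.n_intervals
        area = (
            calendar.area_indicator()[:-1]
            if calendar.dates[0] <= pd.Period("1997-10") <= calendar.dates[-1]
            else np.zeros(n)
        )
        base = pd.DataFrame(
            {
                "time": np.arange(1, n + 1),
                "season": calendar.interval_seasons,
                "year": calendar.interval_years(),
                "area": area,
            }
        )
    if covariates is not None and level == "interval":
        cov = covariates.reset_index(drop=True)
        if len(cov) != n:
            raise ValueError(
                f"covariate table has {len(cov)} rows, calendar has {n} intervals"
            )
        for c in cov.columns:
            base[c] = cov[c].to_numpy()
    frames = []
    for g in groups:
        f = base.copy()
        f["sex"] = g
        f["group"] = g
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def _encode_term(
    term: tuple[str, ...], feats: pd.DataFrame, drop_first_time: bool
) -> tuple[np.ndarray, list[str]]:
    """Columns for one term: product over its factors' encodings."""
    blocks: list[tuple[np.ndarray, list[str]]] = []
    for fac in term:
        if fac in _FACTORS:
            levels = list(pd.unique(feats[fac]))
            if fac in _FULL_RANK_FACTORS and len(term) == 1 and not drop_first_time:
                use = levels  # full one-hot, absorbs the intercept
            else:
                use = levels[1:]  # treatment coding
            cols = np.column_stack(
                [(feats[fac] == lv).to_numpy(float) for lv in use]
            ) if use else np.zeros((len(feats), 0))
            names = [f"{fac}[{lv}]" for lv in use]
        else:
            if fac not in feats.columns:
                raise KeyError(f"unknown covariate {fac!r} in formula")
            cols = feats[[fac]].to_numpy(float)
            names = [fac]
        blocks.append((cols, names))
    out_cols, out_names = blocks[0]
    for cols, names in blocks[1:]:
        out_cols = np.einsum("ij,ik->ijk", out_cols, cols).reshape(len(feats), -1)
        out_names = [f"{a}:{b}" for a in out_names for b in names]
    return out_cols, out_names


@dataclass
class ParamDesign:
    """Design matrix for one model parameter across all groups."""

    param: str
    formula: str
    X: np.ndarray  # (G * n_units, K_param)
    colnames: list[str]
    n_units: int  # occasions or intervals per group
    groups: list[str]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def group_block(self, g: int) -> np.ndarray:
        return self.X[g * self.n_units : (g + 1) * self.n_units]


def compile_parameter_design(
    param: str,
    formula: str,
    calendar: OccasionCalendar,
    groups: list[str],
    covariates: pd.DataFrame | None = None,
) -> ParamDesign:
    level = "occasion" if param == "p" else "interval"
    feats = _feature_frame(calendar, level, groups, covariates)
    terms = parse_formula(formula)
    has_full = any(len(t) == 1 and t[0] in _FULL_RANK_FACTORS for t in terms)
    cols: list[np.ndarray] = []
    names: list[str] = []
    if not has_full:
        cols.append(np.ones((len(feats), 1)))
        names.append("(Intercept)")
    for term in terms:
        c, n = _encode_term(term, feats, drop_first_time=False)
        cols.append(c)
        names.extend(n)
    X = np.hstack(cols)
    return ParamDesign(param, formula, X, names, len(feats) // len(groups), groups)


def compile_design(
    spec: PradelModelSpec,
    calendar: OccasionCalendar,
    groups: list[str],
    covariates: pd.DataFrame | None = None,
) -> dict[str, ParamDesign]:
    """Design matrices for every parameter of ``spec``; K = sum of columns.

    Raises if any single-parameter design is rank deficient (composite
    confounding across parameters is reported at fit time from the Hessian
    rank instead).
    """
    if covariates is not None and spec.standardize_covariates:
        covariates = (covariates - covariates.mean()) / covariates.std(ddof=1)
    designs = {}
    for param in spec.param_names:
        d = compile_parameter_design(
            param, spec.formula(param), calendar, groups, covariates
        )
        rank = np.linalg.matrix_rank(d.X) if d.X.size else 0
        if rank < d.k:
            dep = d.colnames[rank:]
            raise ValueError(
                f"design for {param}({d.formula}) is rank deficient "
                f"(rank {rank} < {d.k}); check columns {dep}"
            )
        designs[param] = d
    return designs


def total_k(designs: dict[str, ParamDesign]) -> int:
    return sum(d.k for d in designs.values())
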