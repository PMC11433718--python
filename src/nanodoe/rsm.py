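"""Quadratic response-surface modelling on coded designs.

Fits the full second-order polynomial

    y = b0 + sum_i bi xi + sum_{i<j} bij xi xj + sum_i bii xi^2

by ordinary least squares, decomposes the fit into a Design-Expert-style
ANOVA table (per-term partial sums of squares, lack of fit vs pure error
from replicated center points), and locates the constrained optimum of the
fitted surface over the coded cube [-1, +1]^m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .designs import DesignMatrix, FactorSpec, uncode_levels

__all__ = [
    "QuadraticFit",
    "AnovaRow",
    "Optimum",
    "quadratic_terms",
    "fit_quadratic",
    "anova_decompose",
    "find_optimum",
    "predict",
]


class SingularDesignError(ValueError):
    """Model matrix is rank deficient: the design cannot support a full quadratic."""


def quadratic_terms(x: np.ndarray, names: list[str]) -> pd.DataFrame:
    """Expand coded factor columns into the full quadratic model matrix.

    Column order: intercept, linear terms, pairwise interactions (lexicographic
    pairs), then squared terms.
    """
    x = np.asarray(x, dtype=float)
    m = x.shape[1]
    cols: dict[str, np.ndarray] = {"const": np.ones(len(x))}
    for i in range(m):
        cols[names[i]] = x[:, i]
    for i, j in combinations(range(m), 2):
        cols[f"{names[i]}:{names[j]}"] = x[:, i] * x[:, j]
    for i in range(m):
        cols[f"{names[i]}^2"] = x[:, i] ** 2
    return pd.DataFrame(cols)


@dataclass
class QuadraticFit:
    """OLS fit of the full quadratic surface on a coded design."""

    factor_names: list[str]
    coef: pd.Series               # indexed by term name, const first
    fitted: np.ndarray
    residuals: np.ndarray
    r2: float
    r2_adjusted: float
    cv_percent: float
    ss_residual: float
    ss_total: float
    df_residual: int
    bse: pd.Series = field(repr=False, default=None)  # coefficient standard errors
    conf_int: pd.DataFrame = field(repr=False, default=None)  # 95% t-intervals

    @property
    def m(self) -> int:
        return len(self.factor_names)

    @property
    def intercept(self) -> float:
        return float(self.coef["const"])

    @property
    def linear(self) -> np.ndarray:
        return self.coef[list(self.factor_names)].to_numpy()

    @property
    def quadratic(self) -> np.ndarray:
        return self.coef[[f"{n}^2" for n in self.factor_names]].to_numpy()

    def interaction(self, i: int, j: int) -> float:
        a, b = sorted((i, j))
        return float(self.coef[f"{self.factor_names[a]}:{self.factor_names[b]}"])

    def hessian(self) -> np.ndarray:
        """Hessian of the fitted polynomial (constant in x)."""
        m = self.m
        h = np.diag(2.0 * self.quadratic)
        for i, j in combinations(range(m), 2):
            h[i, j] = h[j, i] = self.interaction(i, j)
        return h


def _design_xy(design: DesignMatrix | pd.DataFrame | np.ndarray):
    if isinstance(design, DesignMatrix):
        coded = design.coded[design.factor_names]
    elif isinstance(design, pd.DataFrame):
        coded = design
    else:
        arr = np.asarray(design, dtype=float)
        coded = pd.DataFrame(arr, columns=[f"X{i + 1}" for i in range(arr.shape[1])])
    return coded.to_numpy(dtype=float), list(coded.columns)


def fit_quadratic(design: DesignMatrix | pd.DataFrame | np.ndarray, y) -> QuadraticFit:
    """Fit the full quadratic model by OLS on a coded design.

    Raises
    ------
    SingularDesignError
        If the model matrix is rank deficient (e.g. a two-level design that
        cannot separate squared terms).
    ValueError
        If there are not more runs than parameters.
    """
    x, names = _design_xy(design)
    y = np.asarray(y, dtype=float)
    if len(y) != len(x):
        raise ValueError(f"{len(x)} design runs but {len(y)} responses")
    mm = quadratic_terms(x, names)
    n, p = mm.shape
    if n <= p:
        raise ValueError(f"insufficient runs: n={n} <= p={p} parameters")
    if np.linalg.matrix_rank(mm.to_numpy()) < p:
        raise SingularDesignError("rank-deficient quadratic model matrix for this design")

    res = sm.OLS(y, mm).fit()
    ss_res = float(res.ssr)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    df_res = int(res.df_resid)
    ms_res = ss_res / df_res
    ybar = float(y.mean())
    cv = 100.0 * np.sqrt(ms_res) / ybar if ybar != 0 else np.inf
    ci = res.conf_int(alpha=0.05)
    ci.columns = ["lower", "upper"]
    return QuadraticFit(
        factor_names=names,
        coef=res.params,
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
        r2=float(res.rsquared),
        r2_adjusted=float(res.rsquared_adj),
        cv_percent=float(cv),
        ss_residual=ss_res,
        ss_total=ss_tot,
        df_residual=df_res,
        bse=res.bse,
        conf_int=ci,
    )


@dataclass
class AnovaRow:
    source: str
    ss: float
    df: int
    ms: float | None
    f: float | None
    p: float | None


def anova_decompose(fit: QuadraticFit, design: DesignMatrix | pd.DataFrame | np.ndarray,
                    y) -> list[AnovaRow]:
    """ANOVA table for a quadratic fit: model, per-term (partial SS), residual,
    lack of fit, pure error, total.

    Per-term sums of squares are partial (type III): the increase in residual
    SS when that single column is dropped from the full model. Pure error
    comes from replicated runs (identical coded rows, typically the center
    points); its split is omitted with a warning when no run is replicated.
    """
    x, names = _design_xy(design)
    y = np.asarray(y, dtype=float)
    mm = quadratic_terms(x, names).to_numpy()
    term_names = list(quadratic_terms(x, names).columns)[1:]  # skip intercept

    ss_res = fit.ss_residual
    ss_tot = fit.ss_total
    ss_model = ss_tot - ss_res
    df_model = len(term_names)
    df_res = fit.df_residual
    ms_res = ss_res / df_res

    rows: list[AnovaRow] = []
    f_model = (ss_model / df_model) / ms_res
    rows.append(AnovaRow("model", ss_model, df_model, ss_model / df_model,
                         f_model, float(stats.f.sf(f_model, df_model, df_res))))

    for k, term in enumerate(term_names, start=1):
        sub = np.delete(mm, k, axis=1)
        beta, _, _, _ = np.linalg.lstsq(sub, y, rcond=None)
        ss_drop = float(((y - sub @ beta) ** 2).sum()) - ss_res
        f_t = ss_drop / ms_res
        rows.append(AnovaRow(term, ss_drop, 1, ss_drop, f_t,
                             float(stats.f.sf(f_t, 1, df_res))))

    rows.append(AnovaRow("residual", ss_res, df_res, ms_res, None, None))

    # replicate groups -> pure error
    keys = [tuple(r) for r in x]
    groups: dict[tuple, list[int]] = {}
    for i, kk in enumerate(keys):
        groups.setdefault(kk, []).append(i)
    rep = [idx for idx in groups.values() if len(idx) > 1]
    if rep:
        ss_pe = sum(float(((y[idx] - y[idx].mean()) ** 2).sum()) for idx in rep)
        df_pe = sum(len(idx) - 1 for idx in rep)
        ss_lof = ss_res - ss_pe
        df_lof = df_res - df_pe
        if df_lof > 0 and df_pe > 0 and ss_pe > 0:
            f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
        else:  # saturated split or exact replicates (zero pure error)
            f_lof = p_lof = None
        rows.append(AnovaRow("lack of fit", ss_lof, df_lof,
                             ss_lof / df_lof if df_lof > 0 else None, f_lof, p_lof))
        rows.append(AnovaRow("pure error", ss_pe, df_pe,
                             ss_pe / df_pe if df_pe > 0 else None, None, None))
    else:
        warnings.warn("no replicated runs: lack-of-fit/pure-error split omitted",
                      stacklevel=2)

    rows.append(AnovaRow("total", ss_tot, len(y) - 1, None, None, None))
    return rows


def anova_table(rows: list[AnovaRow]) -> pd.DataFrame:
    """ANOVA rows as a DataFrame (convenience for reports)."""
    return pd.DataFrame(
        [{"source": r.source, "SS": r.ss, "df": r.df, "MS": r.ms, "F": r.f, "p": r.p}
         for r in rows]
    ).set_index("source")


@dataclass
class Optimum:
    coded: np.ndarray
    natural: np.ndarray
    natural_rounded: np.ndarray
    predicted: float
    classification: str  # "interior maximum"/"interior minimum"/"boundary maximum"/...


def predict(fit: QuadraticFit, point) -> float:
    """Evaluate the fitted polynomial at one coded point."""
    point = np.asarray(point, dtype=float)
    if point.shape != (fit.m,):
        raise ValueError(f"expected a point of dimension {fit.m}, got shape {point.shape}")
    val = fit.intercept + fit.linear @ point + fit.quadratic @ (point ** 2)
    for i, j in combinations(range(fit.m), 2):
        val += fit.interaction(i, j) * point[i] * point[j]
    return float(val)


def _round_half_away(x: np.ndarray, step: np.ndarray) -> np.ndarray:
    """Round to the nearest multiple of step, halves away from zero."""
    q = x / step
    return np.where(q >= 0, np.floor(q + 0.5), np.ceil(q - 0.5)) * step


def stationary_point(fit: QuadraticFit) -> np.ndarray:
    """Solve grad y-hat = 0: H x = -b_linear."""
    return np.linalg.solve(fit.hessian(), -fit.linear)


def find_optimum(fit: QuadraticFit, specs: list[FactorSpec], goal: str = "maximize",
                 rounding_step: float | np.ndarray = 0.1,
                 grid_step: float = 0.01) -> Optimum:
    """Locate the optimum of the fitted surface over the coded cube [-1, 1]^m.

    The stationary point of the quadratic is used directly when it lies inside
    the cube and the Hessian is definite in the goal's direction; otherwise a
    dense grid search (refined by a bounded local polish) finds the boundary
    optimum. Natural-unit coordinates are reported both raw and rounded
    half-away-from-zero to ``rounding_step`` (per factor), matching how
    process settings are quoted.
    """
    if goal not in ("maximize", "minimize"):
        raise ValueError("goal must be 'maximize' or 'minimize'")
    sign = 1.0 if goal == "maximize" else -1.0
    m = fit.m
    h = fit.hessian()

    coded = None
    classification = None
    try:
        xs = np.linalg.solve(h, -fit.linear)
        eig = np.linalg.eigvalsh(h)
        definite = np.all(sign * eig < -1e-10)  # negative definite when maximizing
        if definite and np.all(np.abs(xs) <= 1.0 + 1e-12):
            coded = np.clip(xs, -1.0, 1.0)
            classification = f"interior {'maximum' if sign > 0 else 'minimum'}"
    except np.linalg.LinAlgError:
        classification = "saddle-fallback"

    if coded is None:
        # dense grid (vectorized) then local polish on the cube
        axes = [np.arange(-1.0, 1.0 + grid_step / 2, grid_step)] * m
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, m)
        vals = fit.intercept + mesh @ fit.linear + (mesh ** 2) @ fit.quadratic
        for i, j in combinations(range(m), 2):
            vals += fit.interaction(i, j) * mesh[:, i] * mesh[:, j]
        x0 = mesh[np.argmax(sign * vals)]
        res = optimize.minimize(lambda p: -sign * predict(fit, p), x0,
                                bounds=[(-1.0, 1.0)] * m, method="L-BFGS-B")
        coded = res.x
        if classification is None:
            classification = f"boundary {'maximum' if sign > 0 else 'minimum'}"

    natural = uncode_levels(coded, specs)
    step = np.broadcast_to(np.asarray(rounding_step, dtype=float), (m,))
    return Optimum(
        coded=coded,
        natural=natural,
        natural_rounded=_round_half_away(natural, step),
        predicted=predict(fit, coded),
        classification=classification,
    )
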