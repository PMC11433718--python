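"""Main-effects ANOVA for 12-run Plackett-Burman screening experiments.

For each response, the effect of a factor is the mean response at its +1
level minus the mean at its -1 level. On the orthogonal 12-run design the
associated sum of squares is N * effect^2 / 4 = 3 * effect^2. Dummy columns
(unassigned design columns) are pooled into the residual, giving
11 - n_factors residual degrees of freedom for F tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .designs import DesignMatrix

__all__ = ["screen", "ScreeningResult"]


class CannotTestError(ValueError):
    """No residual degrees of freedom: drop factors or add replicates."""


@dataclass
class ScreeningResult:
    """Per-response factor effects, F statistics, p values and significance flags."""

    effects: pd.DataFrame      # factors x responses, ybar(+1) - ybar(-1)
    ss: pd.DataFrame           # factors x responses
    f: pd.DataFrame            # factors x responses
    p: pd.DataFrame            # factors x responses
    model: pd.DataFrame        # rows SS/df/F/p per response (all factors jointly)
    significant: pd.DataFrame  # booleans, p < alpha
    alpha: float
    df_residual: int

    def ranked(self, response: str) -> pd.Series:
        """Factors ordered by |effect| for one response, largest first."""
        return self.effects[response].abs().sort_values(ascending=False)


def screen(design: DesignMatrix, responses: pd.DataFrame, alpha: float = 0.05) -> ScreeningResult:
    """Main-effects screening ANOVA on a 12-run Plackett-Burman design.

    Parameters
    ----------
    design : DesignMatrix
        A ``make_pbd`` design; its dummy columns provide the error estimate.
    responses : DataFrame
        One row per run (aligned with the design), one column per response.
    alpha : float
        Significance level for the per-factor flags.
    """
    if design.kind != "pbd":
        raise ValueError("screening requires a Plackett-Burman design")
    if len(responses) != design.n_runs:
        raise ValueError(f"{design.n_runs} runs in design but {len(responses)} response rows")
    factors = design.factor_names
    n = design.n_runs
    df_res = (n - 1) - len(factors)
    if df_res < 1:
        raise CannotTestError(
            f"{len(factors)} factors in {n} runs leave no residual df; "
            "screen fewer factors or add replicate runs"
        )

    x = design.coded[factors].to_numpy(dtype=float)
    eff = pd.DataFrame(index=factors, columns=responses.columns, dtype=float)
    ss = eff.copy()
    fstat = eff.copy()
    pval = eff.copy()
    model_rows = {}
    for resp in responses.columns:
        y = responses[resp].to_numpy(dtype=float)
        e = np.array([y[x[:, j] > 0].mean() - y[x[:, j] < 0].mean() for j in range(len(factors))])
        s = n * e ** 2 / 4.0
        ss_tot = float(((y - y.mean()) ** 2).sum())
        ss_resid = ss_tot - float(s.sum())
        ss_resid = max(ss_resid, 0.0)  # guard tiny negative from rounding
        ms_resid = ss_resid / df_res
        with np.errstate(divide="ignore", invalid="ignore"):
            # zero residual: F is infinite for nonzero effects, undefined (and
            # not significant) for exactly zero effects
            f = np.where(ms_resid > 0, s / ms_resid, np.where(s > 0, np.inf, np.nan))
        eff[resp] = e
        ss[resp] = s
        fstat[resp] = f
        pval[resp] = stats.f.sf(f, 1, df_res)
        ss_model = float(s.sum())
        if ms_resid > 0:
            f_model = (ss_model / len(factors)) / ms_resid
        else:
            f_model = np.inf if ss_model > 0 else np.nan
        model_rows[resp] = {
            "SS": ss_model, "df": len(factors), "F": f_model,
            "p": float(stats.f.sf(f_model, len(factors), df_res)),
            "SS_residual": ss_resid, "df_residual": df_res, "SS_total": ss_tot,
        }

    return ScreeningResult(
        effects=eff, ss=ss, f=fstat, p=pval,
        model=pd.DataFrame(model_rows).T,
        significant=pval < alpha,
        alpha=alpha,
        df_residual=df_res,
    )
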