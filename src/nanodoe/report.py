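"""End-to-end report: desirability scoring -> quadratic fit -> ANOVA -> optimum."""

from __future__ import annotations

import pandas as pd

from .desirability import compute_od
from .designs import DesignMatrix
from .io import RunConfig
from .rsm import anova_decompose, find_optimum, fit_quadratic

__all__ = ["run_report", "report_markdown"]


def run_report(config: RunConfig, table: pd.DataFrame) -> dict:
    """Chain the full analysis on a merged design+response table.

    ``table`` must hold the coded design columns (named as in
    ``config.factors``) plus every response column named in
    ``config.orientations``. Returns a plain dict (JSON-ready via
    :func:`nanodoe.io.dump_json`).
    """
    factor_names = [f.name for f in config.factors]
    missing = [c for c in factor_names if c not in table.columns]
    if missing:
        raise ValueError(f"design columns missing from table: {missing}")
    responses = table[list(config.orientations)]
    design = DesignMatrix(kind="bbd", coded=table[factor_names])

    des = compute_od(responses, config.orientations)
    fit = fit_quadratic(design, des.od.to_numpy())
    rows = anova_decompose(fit, design, des.od.to_numpy())
    opt = find_optimum(fit, config.factor_specs(), goal=config.goal,
                       rounding_step=config.rounding_step)

    return {
        "desirability": {
            "d": {str(i): {c: float(v) for c, v in r.items()} for i, r in des.d.iterrows()},
            "od": {str(i): float(v) for i, v in des.od.items()},
            "k": des.k,
        },
        "fit": {
            "coefficients": {k: float(v) for k, v in fit.coef.items()},
            "r2": fit.r2,
            "r2_adjusted": fit.r2_adjusted,
            "cv_percent": fit.cv_percent,
        },
        "anova": [
            {"source": r.source, "SS": r.ss, "df": r.df, "MS": r.ms, "F": r.f, "p": r.p}
            for r in rows
        ],
        "optimum": {
            "coded": list(map(float, opt.coded)),
            "natural": list(map(float, opt.natural)),
            "natural_rounded": list(map(float, opt.natural_rounded)),
            "predicted": opt.predicted,
            "classification": opt.classification,
        },
    }


def _fmt(v, nd=4):
    if v is None:
        return "/"
    return f"{v:.{nd}f}"


def report_markdown(doc: dict) -> str:
    """Human-readable companion to the JSON report (values shown at 4 decimals)."""
    lines = ["# Response-surface report", "", "## ANOVA", "",
             "| source | SS | df | F | p |", "|---|---|---|---|---|"]
    for row in doc["anova"]:
        lines.append(f"| {row['source']} | {_fmt(row['SS'])} | {row['df']} | "
                     f"{_fmt(row['F'])} | {_fmt(row['p'])} |")
    fit = doc["fit"]
    lines += ["", "## Fit", "",
              f"R2 = {_fmt(fit['r2'])}, adjusted R2 = {_fmt(fit['r2_adjusted'])}, "
              f"CV% = {_fmt(fit['cv_percent'], 2)}", "", "Coefficients:"]
    for name, val in fit["coefficients"].items():
        lines.append(f"- {name}: {_fmt(val)}")
    opt = doc["optimum"]
    lines += ["", "## Optimum", "",
              f"- classification: {opt['classification']}",
              f"- coded point: {[round(c, 4) for c in opt['coded']]}",
              f"- natural point: {[round(c, 4) for c in opt['natural']]}",
              f"- reported (rounded): {opt['natural_rounded']}",
              f"- predicted response: {_fmt(opt['predicted'])}"]
    return "\n".join(lines) + "\n"
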