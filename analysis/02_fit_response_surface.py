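#!/usr/bin/env python
"""Fit the quadratic response surface to the Box-Behnken desirability scores.

Ordinary least squares of OD on the coded factors (chitosan concentration X1,
TPP concentration X2, CS:TPP mass ratio X3), full second-order model, with a
Design-Expert-style ANOVA: partial sums of squares per term and a
lack-of-fit/pure-error split from the five replicated center runs. Writes
results/rsm_fit.json and results/rsm_anova.csv.
"""

from nanodoe import datasets
from nanodoe.io import dump_json, write_table
from nanodoe.rsm import anova_decompose, anova_table, fit_quadratic


def main() -> None:
    runs = datasets.load_bbd_runs()
    design = datasets.load_bbd_design()
    od = runs["od"].to_numpy(dtype=float)

    fit = fit_quadratic(design, od)
    rows = anova_decompose(fit, design, od)

    terms = " ".join(f"{v:+.4f}*{k}" for k, v in fit.coef.items() if k != "const")
    print(f"OD = {fit.intercept:.4f} {terms}")
    print(f"R2 = {fit.r2:.4f}, adjusted R2 = {fit.r2_adjusted:.4f}, CV% = {fit.cv_percent:.2f}")

    tab = anova_table(rows)
    print(tab.round(4).to_string())
    write_table(tab, "results/rsm_anova.csv", float_format="%.6f")
    dump_json({
        "coefficients": {k: float(v) for k, v in fit.coef.items()},
        "r2": fit.r2, "r2_adjusted": fit.r2_adjusted, "cv_percent": fit.cv_percent,
        "anova": [{"source": r.source, "SS": r.ss, "df": r.df, "MS": r.ms,
                   "F": r.f, "p": r.p} for r in rows],
    }, "results/rsm_fit.json")
    print("wrote results/rsm_fit.json, results/rsm_anova.csv")


if __name__ == "__main__":
    main()
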