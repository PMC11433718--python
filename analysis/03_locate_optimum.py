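#!/usr/bin/env python
"""Locate the optimal formulation on the fitted desirability surface.

Solves the stationary system of the quadratic fit, checks it is an interior
maximum of the coded cube, translates it to natural units via the three-level
factor map, and rounds to practical 0.1 reporting steps. Writes
results/optimum.json.
"""

from nanodoe import datasets
from nanodoe.io import dump_json
from nanodoe.rsm import find_optimum, fit_quadratic


def main() -> None:
    runs = datasets.load_bbd_runs()
    design = datasets.load_bbd_design()
    specs = datasets.load_bbd_factor_specs()

    fit = fit_quadratic(design, runs["od"].to_numpy(dtype=float))
    opt = find_optimum(fit, specs, goal="maximize", rounding_step=0.1)

    print(f"classification: {opt.classification}")
    print(f"coded stationary point: {[round(float(c), 4) for c in opt.coded]}")
    for spec, nat, rounded in zip(specs, opt.natural, opt.natural_rounded):
        print(f"  {spec.name}: {nat:.3f} -> {rounded:g} {spec.units}")
    print(f"predicted OD at optimum: {opt.predicted:.4f}")

    dump_json({
        "coded": list(map(float, opt.coded)),
        "natural": list(map(float, opt.natural)),
        "natural_rounded": list(map(float, opt.natural_rounded)),
        "predicted": opt.predicted,
        "classification": opt.classification,
    }, "results/optimum.json")
    print("wrote results/optimum.json")


if __name__ == "__main__":
    main()
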