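"""Seeded synthetic-data generators mirroring the study's data structure.

Three generators, each a pure function of its parameters and seed:

* BBD response tables: a known quadratic surface evaluated on the coded
  design plus i.i.d. Gaussian noise — what the response-surface fit assumes.
* PBD response tables: additive main effects on the 12-run screening design
  plus noise — what the screening ANOVA assumes.
* Release curves: one of the four kinetic model families evaluated on the
  dialysis time grid plus truncated Gaussian noise.

Default noise levels mirror the real study: the BBD default noise sd is the
root residual mean square of the packaged 17-run experiment (~0.154 on the
OD scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designs import DesignMatrix, make_bbd, make_pbd
from .kinetics import RELEASE_TIMES_H, ReleaseCurve, model_q
from .rsm import quadratic_terms

__all__ = [
    "SurfaceTruth",
    "PUBLISHED_BBD_COEF",
    "DEFAULT_BBD_NOISE_SD",
    "gen_bbd_responses",
    "gen_pbd_responses",
    "gen_release",
]

#: Fitted OD-surface coefficients of the packaged 17-run experiment, in model
#: order (const, X1, X2, X3, X1:X2, X1:X3, X2:X3, X1^2, X2^2, X3^2). Useful
#: as a realistic generator truth.
PUBLISHED_BBD_COEF = np.array([
    0.7588, -0.1362, 0.0767, -0.1491, 0.1129, -0.1476, 0.0442,
    -0.2556, -0.0907, -0.1192,
])

#: sqrt(residual mean square) of the packaged 17-run OD fit.
DEFAULT_BBD_NOISE_SD = 0.154


@dataclass(frozen=True)
class SurfaceTruth:
    """Ground truth for a simulated quadratic response surface.

    ``coef`` follows the model-matrix order of :func:`nanodoe.rsm.quadratic_terms`:
    intercept, m linear terms, m(m-1)/2 interactions (lexicographic pairs),
    m squared terms.
    """

    m: int
    coef: tuple
    noise_sd: float = DEFAULT_BBD_NOISE_SD
    seed: int = 0

    def __post_init__(self):
        want = 1 + 2 * self.m + self.m * (self.m - 1) // 2
        if len(self.coef) != want:
            raise ValueError(f"coef must have length {want} for m={self.m}, got {len(self.coef)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def gen_bbd_responses(truth: SurfaceTruth, n_center: int = 5) -> tuple[DesignMatrix, np.ndarray]:
    """Simulate one Box-Behnken experiment from a known quadratic surface."""
    if truth.m != 3:
        raise ValueError("the Box-Behnken generator is specific to 3 factors")
    design = make_bbd(n_center=n_center)
    mm = quadratic_terms(design.coded.to_numpy(dtype=float), design.factor_names)
    y = mm.to_numpy() @ np.asarray(truth.coef, dtype=float)
    rng = np.random.default_rng(truth.seed)
    y = y + rng.normal(0.0, truth.noise_sd, size=len(y))
    return design, y


def gen_pbd_responses(effects: dict[str, float], noise_sd: float, seed: int,
                      n_factors: int = 6,
                      response_name: str = "y") -> tuple[DesignMatrix, pd.DataFrame]:
    """Simulate one Plackett-Burman screening response with known active effects.

    ``effects`` maps factor names (subset of the design's real factors) to
    their +1-vs-minus-1 effect sizes; y = sum(effect/2 * x) + Normal(0, sd).
    """
    design = make_pbd(n_factors)
    unknown = set(effects) - set(design.factor_names)
    if unknown:
        raise ValueError(f"effects given for unknown factors {sorted(unknown)}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    y = np.zeros(design.n_runs)
    for name, eff in effects.items():
        y += (eff / 2.0) * design.coded[name].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    y = y + rng.normal(0.0, noise_sd, size=len(y))
    return design, pd.DataFrame({response_name: y}, index=design.coded.index)


def gen_release(model: str, params: dict[str, float], times=RELEASE_TIMES_H,
                noise_sd: float = 0.0, seed: int = 0, monotonize: bool = False,
                zero_at_origin: bool = True, medium: str = "") -> ReleaseCurve:
    """Simulate a cumulative-release curve from a named kinetic model.

    Noise is Gaussian, truncated so Q stays in [0, 100]. With
    ``zero_at_origin`` (default) the t = 0 point is pinned at Q = 0, as a
    dialysis experiment measures it. ``monotonize`` applies a running maximum
    after noising.
    """
    t = np.asarray(times, dtype=float)
    q = model_q(model, params, t)
    if np.any(q < -1e-9):
        raise ValueError(f"params produce negative release: {params}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if noise_sd > 0:
        # truncate the *noisy* values into [0, 100]; a noiseless model value
        # is returned as-is so generate->fit round trips are exact
        rng = np.random.default_rng(seed)
        q = np.clip(q + rng.normal(0.0, noise_sd, size=len(q)), 0.0, 100.0)
    if zero_at_origin:
        q[t == 0] = 0.0
    if monotonize:
        q = np.maximum.accumulate(q)
    return ReleaseCurve(times=t, q=q, medium=medium)
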