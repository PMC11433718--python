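"""Composite desirability scoring for multi-response designs.

Each response is min-max normalized to [0, 1] over the analyzed runs
(Hassan's method), oriented so that larger d is always better:

    maximize:  d = (y - ymin) / (ymax - ymin)
    minimize:  d = (ymax - y) / (ymax - ymin)

The overall desirability of a run is the geometric mean of its k per-response
d values, OD = (d1 d2 ... dk)^(1/k). A run that is worst-in-column for any
response has d = 0 there and hence OD = 0; a run that is best-in-column for
every response has OD = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["normalize_hassan", "compute_od", "DesirabilityResult", "DegenerateColumnError"]

_ORIENTATIONS = ("maximize", "minimize")


class DegenerateColumnError(ValueError):
    """A response column is constant, so min-max normalization is undefined."""


def normalize_hassan(y, ymin: float, ymax: float, orientation: str):
    """Min-max desirability of ``y`` given column extremes and an orientation.

    Accepts scalars or arrays; values must lie within [ymin, ymax].
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}, got {orientation!r}")
    if not ymin < ymax:
        raise DegenerateColumnError(f"degenerate response column: ymin={ymin} >= ymax={ymax}")
    y = np.asarray(y, dtype=float)
    if np.any(y < ymin) or np.any(y > ymax):
        raise ValueError(f"value outside [{ymin}, {ymax}]")
    if orientation == "maximize":
        d = (y - ymin) / (ymax - ymin)
    else:
        d = (ymax - y) / (ymax - ymin)
    return float(d) if d.ndim == 0 else d


@dataclass
class DesirabilityResult:
    d: pd.DataFrame       # runs x responses, each in [0, 1]
    od: pd.Series         # geometric mean per run
    k: int                # number of responses


def compute_od(responses: pd.DataFrame, orientations: dict[str, str]) -> DesirabilityResult:
    """Score every run of a response table by overall desirability.

    Parameters
    ----------
    responses : DataFrame
        One row per run, one numeric column per response. Extremes are taken
        per column over these rows (the analyzed design itself), not from
        user-supplied bounds.
    orientations : dict
        ``{"particle size": "minimize", "EE": "maximize", ...}`` — must cover
        every column of ``responses``.
    """
    missing = [c for c in responses.columns if c not in orientations]
    if missing:
        raise ValueError(f"no orientation given for response column(s) {missing}")
    if responses.isna().any().any():
        raise ValueError("response table contains missing values")

    d = pd.DataFrame(index=responses.index)
    for col in responses.columns:
        y = responses[col].to_numpy(dtype=float)
        d[col] = normalize_hassan(y, float(y.min()), float(y.max()), orientations[col])

    # geometric mean via exp-mean-log, short-circuiting exact zeros so no
    # log(0) is ever taken
    dm = d.to_numpy()
    any_zero = (dm == 0.0).any(axis=1)
    od = np.zeros(len(d))
    if (~any_zero).any():
        od[~any_zero] = np.exp(np.log(dm[~any_zero]).mean(axis=1))
    return DesirabilityResult(d=d, od=pd.Series(od, index=responses.index, name="OD"),
                              k=responses.shape[1])
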