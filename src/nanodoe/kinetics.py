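"""Drug-release curves and kinetic model fitting.

Cumulative release from replacement dialysis sampling:

    Q_n = 100 * (C_n * V + v * sum_{i<n} C_i) / m

where C_n is the sampled concentration at time n, V the vessel volume, v the
withdrawn-and-replaced sample volume and m the loaded drug mass.

Four empirical model families describe the cumulative-release profile Q(t)
(Q in percent, t in hours):

    zero-order      Q = Q0 + k0 t
    first-order     Q = Qinf (1 - exp(-k1 t))         (plateau form)
    Higuchi         Q = kH sqrt(t) + c                (intercept optional)
    Ritger-Peppas   Q = kP t^n

The release exponent n of the power law diagnoses the transport mechanism
(n ~ 0.5 is Fickian diffusion; the power law reduces to an intercept-free
Higuchi model at n = 0.5). Goodness of fit is R^2 on the untransformed Q
scale for every family so that linearizable and intrinsically nonlinear
models are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "RELEASE_TIMES_H",
    "MODEL_NAMES",
    "ReleaseCurve",
    "KineticFit",
    "cumulative_release",
    "fit_model",
    "select_best",
    "model_q",
]

#: Dialysis sampling grid (hours) used throughout: dense early sampling to
#: resolve the burst phase, then spreading out to 48 h.
RELEASE_TIMES_H = (0.0, 0.25, 0.5, 0.75, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0)

#: Fixed model order; also the tie-break preference in :func:`select_best`
#: (earlier = structurally simpler).
MODEL_NAMES = ("zero-order", "first-order", "higuchi", "ritger-peppas")


class FitFailureError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best attempt if any."""

    def __init__(self, message: str, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt


@dataclass
class ReleaseCurve:
    """Cumulative release (percent of loaded drug) over time (hours)."""

    times: np.ndarray
    q: np.ndarray
    medium: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.times.shape != self.q.shape:
            raise ValueError("times and release values differ in length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be nondecreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times, "Q_percent": self.q})


@dataclass
class KineticFit:
    model: str
    params: dict[str, float]
    r2: float
    sse: float
    fitted: np.ndarray = field(repr=False, default=None)


def cumulative_release(concentrations, vessel_volume: float, sample_volume: float,
                       drug_mass: float, times=None, medium: str = "") -> ReleaseCurve:
    """Cumulative release (%) from sampled concentrations with replacement
    correction.

    ``concentrations`` are mg/mL at each sampling time; each withdrawn aliquot
    of ``sample_volume`` mL is replaced with fresh medium, so drug removed in
    earlier aliquots is added back when computing later cumulative amounts.
    """
    if vessel_volume <= 0 or sample_volume < 0 or drug_mass <= 0:
        raise ValueError("volumes and drug mass must be positive")
    c = np.asarray(concentrations, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    removed = sample_volume * np.concatenate([[0.0], np.cumsum(c)[:-1]])
    q = 100.0 * (c * vessel_volume + removed) / drug_mass
    if np.any(q > 100.0):
        warnings.warn("cumulative release exceeds 100% (not clipped): check inputs",
                      stacklevel=2)
    if times is None:
        times = np.arange(len(c), dtype=float)
    return ReleaseCurve(times=np.asarray(times, dtype=float), q=q, medium=medium)


def _zero_order(t, q0, k0):
    return q0 + k0 * t


def _first_order(t, qinf, k1):
    return qinf * (1.0 - np.exp(-k1 * t))


def _higuchi(t, kh, c):
    return kh * np.sqrt(t) + c


def _peppas(t, kp, n):
    return kp * np.power(t, n, where=t > 0, out=np.zeros_like(np.asarray(t, dtype=float)))


def model_q(model: str, params: dict[str, float], t) -> np.ndarray:
    """Evaluate a named release model at times ``t`` (hours)."""
    t = np.asarray(t, dtype=float)
    if model == "zero-order":
        return _zero_order(t, params["Q0"], params["k0"])
    if model == "first-order":
        return _first_order(t, params["Qinf"], params["k1"])
    if model == "higuchi":
        return _higuchi(t, params["kH"], params.get("c", 0.0))
    if model == "ritger-peppas":
        return _peppas(t, params["kP"], params["n"])
    raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")


def _init_first_order(t, q):
    """Linearized start: regress log(1 - Q/Qinf_guess) on t."""
    qinf0 = min(max(q.max() * 1.05, 1e-6), 100.0)
    mask = (t > 0) & (q < qinf0)
    if mask.sum() >= 2:
        z = np.log1p(-q[mask] / qinf0)
        k0 = max(-np.polyfit(t[mask], z, 1)[0], 1e-6)
    else:
        k0 = 0.1
    return qinf0, k0


def _init_peppas(t, q):
    """Log-log regression start for Q = kP t^n."""
    mask = (t > 0) & (q > 0)
    if mask.sum() >= 2:
        n, logk = np.polyfit(np.log(t[mask]), np.log(q[mask]), 1)
        return max(np.exp(logk), 1e-6), min(max(n, 1e-3), 2.0)
    return 10.0, 0.5


def fit_model(curve: ReleaseCurve, model: str, higuchi_intercept: bool = True) -> KineticFit:
    """Least-squares fit of one kinetic model family to a release curve.

    Initialization comes from the model's linearization (log for first-order,
    log-log for the power law); t = 0 points are excluded from initialization
    but kept in the nonlinear objective. The power law is fit on t > 0 points
    only (its value at t = 0 is identically 0).
    """
    t, q = curve.times, curve.q
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")
    min_pts = 4 if model == "first-order" else 3
    if (t > 0).sum() < min_pts:
        raise ValueError(f"{model} needs >= {min_pts} points with t > 0")

    if model == "ritger-peppas":
        mask = t > 0
        tt, qq = t[mask], q[mask]
    else:
        tt, qq = t, q

    try:
        if model == "zero-order":
            popt, _ = curve_fit(_zero_order, tt, qq, p0=[qq[0], 1.0])
            params = {"Q0": popt[0], "k0": popt[1]}
            fitted = _zero_order(tt, *popt)
        elif model == "first-order":
            p0 = _init_first_order(tt, qq)
            popt, _ = curve_fit(_first_order, tt, qq, p0=p0,
                                bounds=([1e-9, 1e-9], [100.0, np.inf]), maxfev=20000)
            params = {"Qinf": popt[0], "k1": popt[1]}
            fitted = _first_order(tt, *popt)
        elif model == "higuchi":
            if higuchi_intercept:
                popt, _ = curve_fit(_higuchi, tt, qq, p0=[10.0, 0.0])
                params = {"kH": popt[0], "c": popt[1]}
            else:
                popt, _ = curve_fit(lambda t_, kh: kh * np.sqrt(t_), tt, qq, p0=[10.0])
                params = {"kH": popt[0], "c": 0.0}
            fitted = _higuchi(tt, params["kH"], params["c"])
        else:  # ritger-peppas
            p0 = _init_peppas(tt, qq)
            popt, _ = curve_fit(lambda t_, kp, n: kp * t_ ** n, tt, qq, p0=p0,
                                bounds=([1e-9, 1e-9], [np.inf, 5.0]), maxfev=20000)
            params = {"kP": popt[0], "n": popt[1]}
            fitted = popt[0] * tt ** popt[1]
    except RuntimeError as exc:  # scipy non-convergence
        raise FitFailureError(f"{model} fit did not converge: {exc}") from exc

    resid = qq - fitted
    sse = float(resid @ resid)
    sst = float(((qq - qq.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    return KineticFit(model=model, params={k: float(v) for k, v in params.items()},
                      r2=float(r2), sse=sse, fitted=fitted)


def select_best(curve: ReleaseCurve, higuchi_intercept: bool = True,
                tie_tol: float = 1e-9) -> KineticFit:
    """Fit all four model families and return the best by R^2.

    R^2 ties (within ``tie_tol``) break toward the earlier entry of
    ``MODEL_NAMES`` — the structurally simpler family. Individual fit
    failures are skipped with a warning; only all four failing is an error.
    """
    fits: list[KineticFit] = []
    for name in MODEL_NAMES:
        try:
            fits.append(fit_model(curve, name, higuchi_intercept=higuchi_intercept))
        except (FitFailureError, ValueError) as exc:
            warnings.warn(f"skipping {name}: {exc}", stacklevel=2)
    if not fits:
        raise FitFailureError("all four kinetic model fits failed")
    best_r2 = max(f.r2 for f in fits)
    for f in fits:  # MODEL_NAMES order preserved
        if f.r2 >= best_r2 - tie_tol:
            return f
    raise AssertionError("unreachable")
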