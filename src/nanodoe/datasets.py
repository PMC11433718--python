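"""Packaged reference datasets for the chitosan-nanoparticle optimization study.

Small CSV snapshots shipped with the package:

* ``bbd_runs.csv`` — the 17-run Box-Behnken experiment: coded levels of the
  chitosan concentration (X1), TPP concentration (X2) and CS:TPP mass ratio
  (X3), the four measured responses (particle size, zeta potential,
  encapsulation efficiency, drug loading) and the published overall
  desirability (OD) per run.
* ``bbd_factor_levels.csv`` / ``pbd_factor_levels.csv`` — natural-unit level
  maps for the Box-Behnken and Plackett-Burman factors.
* ``release_equations.csv`` — fitted release-kinetics parameters per medium
  and model family (used as generator ground truth).
* ``mannitol_series.csv`` — lyoprotectant (mannitol) screening series.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .designs import DesignMatrix, FactorSpec

__all__ = [
    "load_bbd_runs",
    "load_bbd_design",
    "load_bbd_responses",
    "BBD_ORIENTATIONS",
    "load_bbd_factor_specs",
    "load_pbd_factor_specs",
    "load_release_equations",
    "release_params",
    "load_mannitol_series",
]

#: Response orientations for the overall-desirability score: small particles,
#: high zeta potential (colloidal stability), high encapsulation and loading.
BBD_ORIENTATIONS = {
    "particle_size_nm": "minimize",
    "potential_mV": "maximize",
    "ee_percent": "maximize",
    "dl_percent": "maximize",
}

RESPONSE_COLUMNS = list(BBD_ORIENTATIONS)


def _read(name: str) -> pd.DataFrame:
    with resources.files("nanodoe.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_bbd_runs() -> pd.DataFrame:
    """The 17-run BBD table, indexed by run id."""
    return _read("bbd_runs.csv").set_index("run")


def load_bbd_design() -> DesignMatrix:
    """Coded design portion of the packaged BBD table."""
    coded = load_bbd_runs()[["X1", "X2", "X3"]].astype(int)
    return DesignMatrix(kind="bbd", coded=coded)


def load_bbd_responses() -> pd.DataFrame:
    """The four measured response columns of the packaged BBD table."""
    return load_bbd_runs()[RESPONSE_COLUMNS]


def _specs_from_frame(df: pd.DataFrame) -> list[FactorSpec]:
    out = []
    for _, r in df.iterrows():
        center = r["center"] if "center" in df.columns and not pd.isna(r.get("center")) else None
        out.append(FactorSpec(name=r["name"], units=str(r["units"]), low=float(r["low"]),
                              high=float(r["high"]),
                              center=None if center is None else float(center)))
    return out


def load_bbd_factor_specs() -> list[FactorSpec]:
    """Three-level factor maps: X1 chitosan mg/mL, X2 TPP mg/mL, X3 CS:TPP ratio."""
    return _specs_from_frame(_read("bbd_factor_levels.csv"))


def load_pbd_factor_specs() -> list[FactorSpec]:
    """Two-level screening factor maps A-F (CS, TPP, ratio, drug dose, HA, stir time)."""
    return _specs_from_frame(_read("pbd_factor_levels.csv"))


def load_release_equations() -> pd.DataFrame:
    """Fitted kinetic parameters per medium and model.

    Columns p1/p2 hold, per model: zero-order (Q0, k0), first-order
    (Qinf, k1), Higuchi (kH, c), Ritger-Peppas (kP, n).
    """
    return _read("release_equations.csv")


_PARAM_NAMES = {
    "zero-order": ("Q0", "k0"),
    "first-order": ("Qinf", "k1"),
    "higuchi": ("kH", "c"),
    "ritger-peppas": ("kP", "n"),
}


def release_params(medium: str, model: str) -> dict[str, float]:
    """Named parameter dict for one medium/model row of the packaged table."""
    df = load_release_equations()
    row = df[(df["medium"] == medium) & (df["model"] == model)]
    if row.empty:
        raise KeyError(f"no packaged equation for medium={medium!r}, model={model!r}")
    names = _PARAM_NAMES[model]
    vals = row.iloc[0]
    return {names[0]: float(vals["p1"]), names[1]: float(vals["p2"])}


def load_mannitol_series() -> pd.DataFrame:
    """Lyoprotectant screening: nanoparticle quality vs mannitol mass fraction."""
    return _read("mannitol_series.csv")
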