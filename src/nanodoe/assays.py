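"""Closed-form assay metrics: encapsulation efficiency, drug loading,
radical-scavenging rates and cell viability.

All formulas operate on raw measured quantities (masses in mg, absorbances
in AU) and return percentages except :func:`cell_viability`, which returns a
ratio.
"""

from __future__ import annotations

__all__ = ["ee_percent", "dl_percent", "dpph_scavenging", "abts_scavenging", "cell_viability"]


def ee_percent(w_total: float, w_dissociate: float) -> float:
    """Encapsulation efficiency: percent of total drug not found free in the
    supernatant, EE% = (W_total - W_dissociate) / W_total * 100."""
    if w_total <= 0:
        raise ValueError("w_total must be positive")
    if not 0 <= w_dissociate <= w_total:
        raise ValueError("w_dissociate must lie in [0, w_total]")
    return (w_total - w_dissociate) / w_total * 100.0


def dl_percent(w_total: float, w_lyophilized: float) -> float:
    """Drug loading: drug mass per unit lyophilized-powder mass,
    DL% = W_total / W_lyophilized * 100."""
    if w_lyophilized <= 0:
        raise ValueError("w_lyophilized must be positive")
    if w_total < 0:
        raise ValueError("w_total must be nonnegative")
    return w_total / w_lyophilized * 100.0


def dpph_scavenging(a0: float, a1: float, a2: float) -> float:
    """DPPH radical scavenging rate (%) = (A0 - A1 + A2) / A0 * 100.

    A0: blank control (medium + DPPH), A1: sample + DPPH, A2: sample control
    (sample + medium) correcting for the sample's own absorbance.
    """
    if a0 <= 0:
        raise ValueError("blank absorbance a0 must be positive")
    if min(a1, a2) < 0:
        raise ValueError("absorbances must be nonnegative")
    return (a0 - a1 + a2) / a0 * 100.0


def abts_scavenging(a0: float, a1: float) -> float:
    """ABTS+ radical scavenging rate (%) = (A0 - A1) / A0 * 100."""
    if a0 <= 0:
        raise ValueError("blank absorbance a0 must be positive")
    if a1 < 0:
        raise ValueError("absorbances must be nonnegative")
    return (a0 - a1) / a0 * 100.0


def cell_viability(od_sample: float, od_control: float, mode: str = "as-printed") -> float:
    """CCK-8 cell viability from optical densities.

    ``mode="as-printed"`` returns (OD_sample - OD_control) / OD_control — the
    relative change versus control (0 for the control itself). ``mode="ratio"``
    returns the conventional OD_sample / OD_control.
    """
    if od_control <= 0:
        raise ValueError("od_control must be positive")
    if od_sample < 0:
        raise ValueError("od_sample must be nonnegative")
    if mode == "as-printed":
        return (od_sample - od_control) / od_control
    if mode == "ratio":
        return od_sample / od_control
    raise ValueError("mode must be 'as-printed' or 'ratio'")
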