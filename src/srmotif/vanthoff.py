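"""Concentration-dependence (Van't Hoff) analysis of duplex melting.

For a non-self-complementary bimolecular duplex the melting temperature
depends on total strand concentration as

    1/Tm = (R / dH) * ln(C_T / 4) + dS / dH

so an ordinary least-squares line of 1/Tm against ln(C_T/4) yields dH
and dS independently of curve shape.  Agreement of this dH with the one
from individual curve fits (conventionally within 10%) is the standard
consistency check that melting really is two-state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from srmotif.constants import GAS_CONSTANT

__all__ = ["VantHoffPoint", "VantHoffResult", "vant_hoff_fit",
           "two_state_check"]


@dataclass(frozen=True)
class VantHoffPoint:
    """One (melting temperature, total strand concentration) observation."""

    tm: float   # Kelvin
    c_t: float  # mol/L

    def __post_init__(self):
        if self.tm <= 0:
            raise ValueError("Tm must be positive (Kelvin); got %g" % self.tm)
        if self.c_t <= 0:
            raise ValueError("C_T must be positive; got %g" % self.c_t)


@dataclass(frozen=True)
class VantHoffResult:
    """Regression outcome: thermodynamic parameters and line diagnostics."""

    dH: float        # kcal/mol
    dS: float        # cal/(mol K)
    slope: float     # K^-1 per ln-unit
    intercept: float  # K^-1
    r: float         # Pearson correlation of the linear fit
    n_points: int


def vant_hoff_fit(points: Sequence[VantHoffPoint]) -> VantHoffResult:
    """OLS regression of 1/Tm on ln(C_T/4).

    Requires at least three points spanning at least a two-fold range of
    concentration.  ``dH = R/slope`` (converted to kcal/mol) and
    ``dS = intercept * dH`` (cal units).
    """
    if len(points) < 3:
        raise ValueError("Van't Hoff analysis needs >= 3 concentrations; "
                         "got %d" % len(points))
    ct = np.array([p.c_t for p in points], dtype=float)
    tm = np.array([p.tm for p in points], dtype=float)
    if ct.max() / ct.min() < 2.0:
        raise ValueError(
            "concentrations span only a %.2f-fold range (< 2-fold); the "
            "regression would be ill-determined" % (ct.max() / ct.min()))
    x = np.log(ct / 4.0)
    y = 1.0 / tm
    fit = stats.linregress(x, y)
    if fit.slope == 0.0:
        raise ValueError("zero slope: Tm shows no concentration dependence")
    dh_cal = GAS_CONSTANT / fit.slope
    ds = fit.intercept * dh_cal
    return VantHoffResult(dH=dh_cal / 1000.0, dS=ds,
                          slope=float(fit.slope),
                          intercept=float(fit.intercept),
                          r=float(fit.rvalue), n_points=len(points))


def two_state_check(dh_curve_fit: float, dh_vant_hoff: float,
                    threshold_percent: float = 10.0):
    """Symmetric percent difference between the two dH estimates.

    ``100 * |dH1 - dH2| / mean(|dH1|, |dH2|)``; the verdict is a pass
    when the difference does not exceed ``threshold_percent`` (the
    conventional two-state criterion is 10%).

    Returns
    -------
    (percent_difference, passed) : tuple of (float, bool)
    """
    if not (np.isfinite(dh_curve_fit) and np.isfinite(dh_vant_hoff)):
        raise ValueError("both dH values must be finite")
    denom = 0.5 * (abs(dh_curve_fit) + abs(dh_vant_hoff))
    if denom == 0.0:
        raise ValueError("cannot compare two zero enthalpies")
    diff = float(100.0 * abs(dh_curve_fit - dh_vant_hoff) / denom)
    return diff, bool(diff <= threshold_percent)
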