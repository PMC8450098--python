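"""Closed-form two-state thermodynamics of bimolecular RNA duplex melting.

Model
-----
A non-self-complementary duplex ``A + B <-> AB`` with both strands at
equimolar concentration (total strand concentration ``C_T``) is assumed to
populate exactly two states.  With temperature-independent formation
enthalpy ``dH`` (kcal/mol) and entropy ``dS`` (cal/(mol K), "entropy
units"), the dissociation constant is the van't Hoff expression

    K_D(T) = exp(dH*1000 / (R*T) - dS / R)

and the fraction of strands in duplex form ``f`` solves the mass-balance
relation ``K_D = C_T * (1 - f)**2 / (2 * f)``.  The observed UV absorbance
is a baseline-weighted mixture of the duplex and single-strand signals,
each a straight line in temperature.

All public functions take temperatures in Kelvin except where explicitly
noted (baselines and I/O use Celsius, the instrument's natural unit);
keeping the exponentials in Kelvin avoids sign mistakes near 0 degrees C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from srmotif.constants import CELSIUS_OFFSET, GAS_CONSTANT, T37_K

__all__ = [
    "ThermoParams",
    "Baselines",
    "dissociation_constant",
    "fraction_duplex",
    "predicted_absorbance",
    "delta_g37",
    "delta_delta_g",
    "dh_from_dg_ds",
    "melting_temperature",
]


@dataclass(frozen=True)
class ThermoParams:
    """Formation enthalpy and entropy of a bimolecular duplex.

    Parameters
    ----------
    dH : float
        Enthalpy of duplex formation in kcal/mol.  Negative for a
        favourable (exothermic) association.
    dS : float
        Entropy of duplex formation in cal/(mol K) ("e.u.").

    Notes
    -----
    The mixed unit convention (kcal for enthalpy, cal for entropy) mirrors
    how optical-melting results are reported in the literature, so printed
    values can be used directly as inputs.  Unit conversion happens only
    inside :func:`delta_g37` and :func:`melting_temperature`.
    """

    dH: float
    dS: float


@dataclass(frozen=True)
class Baselines:
    """Linear absorbance baselines of the duplex and single-strand states.

    ``A_DS(T) = m_ds * T + b_ds`` and ``A_SS(T) = m_ss * T + b_ss`` with
    T in degrees Celsius, slopes in AU/degC and intercepts in AU.  For a
    hyperchromic melt the single-strand line lies above the duplex line
    over the measured range; :meth:`validate_hyperchromic` warns (but does
    not fail) when it does not.
    """

    m_ds: float
    b_ds: float
    m_ss: float
    b_ss: float

    def duplex_absorbance(self, t_celsius):
        return self.m_ds * np.asarray(t_celsius, dtype=float) + self.b_ds

    def single_strand_absorbance(self, t_celsius):
        return self.m_ss * np.asarray(t_celsius, dtype=float) + self.b_ss

    def validate_hyperchromic(self, t_lo_c: float, t_hi_c: float) -> bool:
        """Check A_SS >= A_DS at both ends of the fitted range."""
        grid = np.array([t_lo_c, t_hi_c])
        ok = bool(np.all(self.single_strand_absorbance(grid)
                         >= self.duplex_absorbance(grid)))
        if not ok:
            warnings.warn(
                "single-strand baseline falls below the duplex baseline "
                "inside the fitted range; the melt is not hyperchromic "
                "over [%g, %g] degC" % (t_lo_c, t_hi_c),
                stacklevel=2,
            )
        return ok


def dissociation_constant(params: ThermoParams, t_kelvin):
    """Equilibrium dissociation constant ``K_D`` (mol/L) at temperature T (K).

    ``K_D = exp(dH*1000/(R*T) - dS/R)`` — the reciprocal of the van't Hoff
    association constant.  Strictly positive; monotonically increasing in
    T when ``dH < 0``.
    """
    t = np.asarray(t_kelvin, dtype=float)
    if np.any(t <= 0.0):
        raise ValueError("temperature must be positive (Kelvin); got %r"
                         % (t_kelvin,))
    exponent = (params.dH * 1000.0 / (GAS_CONSTANT * t)
                - params.dS / GAS_CONSTANT)
    out = np.exp(exponent)
    return out if out.ndim else float(out)


def fraction_duplex(params: ThermoParams, t_kelvin, c_total: float):
    """Fraction of total strands in duplex form at temperature T (K).

    Solves ``K_D = C_T (1-f)^2 / (2 f)`` for the unique root ``f`` in
    (0, 1) of the quadratic ``C_T f^2 - 2 (C_T + K_D) f + C_T = 0``.  The
    root is evaluated in the rationalised form

        f = C_T / ( (C_T + K_D) + sqrt((C_T + K_D)^2 - C_T^2) )

    which is numerically stable for both very small and very large K_D.
    """
    if c_total <= 0.0:
        raise ValueError("total strand concentration must be positive; got %g"
                         % c_total)
    kd = dissociation_constant(params, t_kelvin)
    kd = np.asarray(kd, dtype=float)
    s = c_total + kd
    # discriminant (C_T + K_D)^2 - C_T^2 = K_D (K_D + 2 C_T) >= 0 always
    disc = kd * (kd + 2.0 * c_total)
    f = c_total / (s + np.sqrt(disc))
    return f if f.ndim else float(f)


def predicted_absorbance(params: ThermoParams, baselines: Baselines,
                         t_celsius, c_total: float):
    """Two-state model absorbance ``A(T) = (1-f) A_SS(T) + f A_DS(T)``.

    Temperatures are in degrees Celsius here because the baselines are
    parameterised in the instrument's unit; the fraction folded is
    evaluated internally in Kelvin.
    """
    t_c = np.asarray(t_celsius, dtype=float)
    f = fraction_duplex(params, t_c + CELSIUS_OFFSET, c_total)
    a = ((1.0 - f) * baselines.single_strand_absorbance(t_c)
         + f * baselines.duplex_absorbance(t_c))
    return a if np.asarray(a).ndim else float(a)


def delta_g37(params: ThermoParams) -> float:
    """Gibbs free energy of duplex formation at 37 degC, kcal/mol.

    ``dG37 = dH - 310.15 * dS / 1000`` (the division converts the entropy
    from cal to kcal).
    """
    return params.dH - T37_K * params.dS / 1000.0


def dh_from_dg_ds(dg37: float, dS: float) -> float:
    """Invert :func:`delta_g37`: enthalpy from (dG37, dS).

    Exists because published tables often print (dG37, dS) but not dH;
    ``delta_g37(ThermoParams(dh_from_dg_ds(g, s), s))`` returns ``g``
    exactly.
    """
    return dg37 + T37_K * dS / 1000.0


def delta_delta_g(dg_a: float, dg_b: float) -> float:
    """Free-energy difference ``dG_a - dG_b`` (kcal/mol).

    Convenience for comparing duplex variants or buffer conditions;
    negative when condition/variant ``a`` is the more stable one.
    """
    return dg_a - dg_b


def melting_temperature(params: ThermoParams, c_total: float,
                        celsius: bool = True) -> float:
    """Melting temperature of a non-self-complementary duplex.

    ``Tm(K) = dH*1000 / (dS + R ln(C_T/4))``; at this temperature
    ``K_D = C_T/4`` and exactly half of the strands are in duplex form.
    Returned in degrees Celsius by default.

    Raises
    ------
    ValueError
        If the denominator vanishes or the resulting Tm is nonphysical
        (<= 0 K), which happens when dS and the concentration term have
        incompatible signs.
    """
    if c_total <= 0.0:
        raise ValueError("total strand concentration must be positive; got %g"
                         % c_total)
    denom = params.dS + GAS_CONSTANT * np.log(c_total / 4.0)
    if denom == 0.0:
        raise ValueError(
            "dS + R ln(C_T/4) = 0: the two-state Tm diverges for "
            "dS=%g e.u. at C_T=%g M" % (params.dS, c_total))
    tm_k = params.dH * 1000.0 / denom
    if tm_k <= 0.0:
        raise ValueError(
            "nonphysical melting temperature %.2f K from dH=%g kcal/mol, "
            "dS=%g e.u., C_T=%g M (enthalpy and entropy terms have "
            "incompatible signs)" % (tm_k, params.dH, params.dS, c_total))
    return tm_k - CELSIUS_OFFSET if celsius else tm_k


def entropy_from_dh_tm(dh: float, tm_kelvin: float, c_total: float) -> float:
    """Entropy (e.u.) implied by (dH, Tm, C_T) under two-state melting.

    Rearranges the Tm expression: ``dS = dH*1000/Tm - R ln(C_T/4)``.
    Used by the curve fitter, which is parameterised in the better-
    conditioned (dH, Tm) pair.
    """
    if tm_kelvin <= 0.0:
        raise ValueError("Tm must be positive (Kelvin); got %g" % tm_kelvin)
    if c_total <= 0.0:
        raise ValueError("total strand concentration must be positive; got %g"
                         % c_total)
    return dh * 1000.0 / tm_kelvin - GAS_CONSTANT * np.log(c_total / 4.0)
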