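"""Two-state fitting of UV melting curves with sloping linear baselines.

The fitter minimises the sum of squared absorbance residuals over six
parameters: formation enthalpy dH, melting temperature Tm, and the four
baseline coefficients.  The entropy is not a free parameter; it is
derived from (dH, Tm, C_T) through the bimolecular Tm relation, which
keeps the optimisation well conditioned (dH and dS are nearly collinear
when both are free).

Also here: replicate aggregation, the nearest-neighbour extinction
coefficient calculation used to convert high-temperature absorbance into
strand concentration, and the plain-text curve/report formats.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import least_squares

from srmotif.constants import CELSIUS_OFFSET
from srmotif.thermo import (
    Baselines,
    ThermoParams,
    delta_g37,
    entropy_from_dh_tm,
    melting_temperature,
    predicted_absorbance,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MeltingCurve",
    "FitResult",
    "ReplicateSummary",
    "FlatCurveError",
    "fit_two_state",
    "initial_guess",
    "r_squared",
    "average_replicates",
    "extinction_coefficient",
    "concentration_from_absorbance",
    "read_melting_curve",
    "write_melting_curve",
    "write_fit_report",
]


class FlatCurveError(ValueError):
    """Raised when a trace shows no detectable melting transition."""


@dataclass(frozen=True)
class MeltingCurve:
    """One absorbance-versus-temperature trace.

    Temperatures are a strictly increasing grid in degrees Celsius;
    absorbances in AU on the same grid.  ``c_total`` is the total strand
    concentration in mol/L at which the curve was recorded.
    """

    temperatures: np.ndarray
    absorbances: np.ndarray
    c_total: float
    wavelength: float = 260.0
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "absorbances", a)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("temperatures and absorbances must be 1-D "
                             "arrays of equal length")
        if t.size < 20:
            raise ValueError("melting curve needs >= 20 points, got %d"
                             % t.size)
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbances contain missing/non-finite values")
        if self.c_total <= 0:
            raise ValueError("c_total must be positive; got %g" % self.c_total)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a two-state fit of one melting curve."""

    params: ThermoParams
    baselines: Baselines
    c_total: float
    tm_fit: float            # degC, at this curve's own c_total
    r_squared: float
    residuals: np.ndarray    # AU, model minus observed, per point
    converged: bool
    n_evaluations: int = 0
    label: str = ""

    @property
    def dg37(self) -> float:
        return delta_g37(self.params)


@dataclass(frozen=True)
class ReplicateSummary:
    """Unweighted mean and SD of fitted parameters across replicates.

    Because dG37 is linear in (dH, dS), the mean dG37 reported here is
    identical to applying the free-energy relation to the mean dH and
    mean dS (parameter-averaged convention).
    """

    dh_mean: float
    dh_sd: float
    ds_mean: float
    ds_sd: float
    dg37_mean: float
    dg37_sd: float
    tm_mean: float
    tm_sd: float
    n_replicates: int
    n_excluded: int = 0
    label: str = ""


def _edge_line(t: np.ndarray, a: np.ndarray, frac: float, side: str):
    """Least-squares line through the first or last ``frac`` of the range."""
    span = t[-1] - t[0]
    if side == "low":
        mask = t <= t[0] + frac * span
    else:
        mask = t >= t[-1] - frac * span
    if mask.sum() < 2:
        mask = np.zeros_like(mask)
        idx = slice(0, 2) if side == "low" else slice(-2, None)
        mask[idx] = True
    slope, intercept = np.polyfit(t[mask], a[mask], 1)
    resid = a[mask] - (slope * t[mask] + intercept)
    return slope, intercept, float(np.std(resid)), int(mask.sum())


def _smoothed_derivative(t: np.ndarray, a: np.ndarray):
    window = max(3, t.size // 15)
    if window % 2 == 0:
        window += 1
    smooth = uniform_filter1d(a, size=window, mode="nearest")
    return np.gradient(smooth, t), window


def initial_guess(curve: MeltingCurve,
                  baseline_fraction: float = 0.15,
                  fallback_dh: float = -50.0):
    """Starting values for :func:`fit_two_state`.

    Baselines come from straight lines through the first and last 15% of
    the temperature range; Tm0 from the peak of the smoothed numerical
    derivative dA/dT; dH0 from the derivative peak height via the
    bimolecular two-state slope relation ``df/dT|Tm = dH/(6 R Tm^2)``
    (falling back to -50 kcal/mol when the estimate is implausible).

    Raises
    ------
    FlatCurveError
        If the separation between the two edge baselines is
        indistinguishable from the baseline noise, i.e. the trace has no
        transition to fit.
    """
    t = curve.temperatures
    a = curve.absorbances
    m_ds, b_ds, sd_lo, _ = _edge_line(t, a, baseline_fraction, "low")
    m_ss, b_ss, sd_hi, _ = _edge_line(t, a, baseline_fraction, "high")

    deriv, window = _smoothed_derivative(t, a)
    # exclude the smoothing-biased edges from the peak search so a noisy
    # endpoint cannot masquerade as the transition
    margin = window // 2 + 1
    interior = slice(margin, t.size - margin)
    i_peak = margin + int(np.argmax(np.abs(deriv[interior])))
    tm0_c = float(t[i_peak])

    # transition amplitude: gap between the two edge lines at the
    # derivative peak, the cleanest noise-robust signal measure
    amplitude = abs((m_ss * tm0_c + b_ss) - (m_ds * tm0_c + b_ds))
    noise = max(sd_lo, sd_hi)
    if amplitude <= max(8.0 * noise, 1e-4):
        raise FlatCurveError(
            "no detectable melting transition: baseline separation %.2g AU "
            "vs noise %.2g AU for curve %r" % (amplitude, noise, curve.label))

    tm0_k = tm0_c + CELSIUS_OFFSET
    peak = abs(deriv[i_peak] - 0.5 * (m_ds + m_ss))
    from srmotif.constants import GAS_CONSTANT
    dh0 = -6.0 * GAS_CONSTANT * tm0_k ** 2 * peak / amplitude / 1000.0
    if not np.isfinite(dh0) or not (-400.0 < dh0 < -10.0):
        dh0 = fallback_dh
    ds0 = entropy_from_dh_tm(dh0, tm0_k, curve.c_total)
    # ds0 is chosen so that melting_temperature(params0, c_total) == tm0_c,
    # making the Tm starting value recoverable from the returned pair
    return ThermoParams(dh0, ds0), Baselines(m_ds, b_ds, m_ss, b_ss)


def _model(x: np.ndarray, t_c: np.ndarray, c_total: float) -> np.ndarray:
    dh, tm_k, m_ds, b_ds, m_ss, b_ss = x
    ds = entropy_from_dh_tm(dh, tm_k, c_total)
    return predicted_absorbance(
        ThermoParams(dh, ds), Baselines(m_ds, b_ds, m_ss, b_ss),
        t_c, c_total)


def fit_two_state(curve: MeltingCurve,
                  max_iterations: int = 2000,
                  tolerance: float = 1e-10) -> FitResult:
    """Nonlinear least-squares fit of the two-state model to one curve.

    Minimises ``sum((A_obs - A_model)^2)`` over (dH, Tm, m_ds, b_ds,
    m_ss, b_ss); dS is derived from (dH, Tm, C_T).  A result that fails
    the optimiser's convergence test is returned with ``converged=False``
    rather than raised, so replicate aggregation can filter it.

    Raises
    ------
    FlatCurveError
        Propagated from :func:`initial_guess` when the trace has no
        transition.
    """
    params0, base0 = initial_guess(curve)
    tm0_c = melting_temperature(params0, curve.c_total)
    x0 = np.array([params0.dH, tm0_c + CELSIUS_OFFSET,
                   base0.m_ds, base0.b_ds, base0.m_ss, base0.b_ss])
    t = curve.temperatures
    a = curve.absorbances

    def residual(x):
        return _model(x, t, curve.c_total) - a

    sol = least_squares(
        residual, x0, method="lm",
        ftol=tolerance, xtol=tolerance, gtol=tolerance,
        max_nfev=max_iterations,
        x_scale=np.array([50.0, 10.0, 1e-3, 0.1, 1e-3, 0.1]),
    )
    dh, tm_k, m_ds, b_ds, m_ss, b_ss = sol.x
    ds = entropy_from_dh_tm(dh, tm_k, curve.c_total)
    params = ThermoParams(float(dh), float(ds))
    baselines = Baselines(float(m_ds), float(b_ds), float(m_ss), float(b_ss))
    baselines.validate_hyperchromic(t[0], t[-1])

    ss_res = float(np.sum(sol.fun ** 2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero-variance absorbance: R^2 undefined")
    r2 = 1.0 - ss_res / ss_tot

    converged = bool(sol.status > 0)
    if not converged:
        logger.warning("fit of %r did not converge: %s",
                       curve.label, sol.message)
    return FitResult(
        params=params, baselines=baselines, c_total=curve.c_total,
        tm_fit=melting_temperature(params, curve.c_total),
        r_squared=r2, residuals=sol.fun.copy(), converged=converged,
        n_evaluations=int(sol.nfev), label=curve.label)


def r_squared(fit: FitResult, curve: MeltingCurve) -> float:
    """Coefficient of determination of a fit against its own curve."""
    a = curve.absorbances
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero-variance absorbance: R^2 undefined")
    pred = predicted_absorbance(fit.params, fit.baselines,
                                curve.temperatures, curve.c_total)
    ss_res = float(np.sum((a - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def average_replicates(fits: Sequence[FitResult]) -> ReplicateSummary:
    """Unweighted mean +/- SD of parameters across converged replicate fits.

    Non-converged fits are excluded (their count is logged and recorded);
    aggregating zero converged fits is an error.
    """
    kept = [f for f in fits if f.converged]
    n_excluded = len(fits) - len(kept)
    if n_excluded:
        logger.info("excluding %d non-converged fit(s) of %d from averaging",
                    n_excluded, len(fits))
    if not kept:
        raise ValueError("no converged fits to average")
    labels = {f.label for f in kept}
    label = labels.pop() if len(labels) == 1 else ""

    def stats(values):
        v = np.array(values, dtype=float)
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        return float(v.mean()), sd

    dh_m, dh_s = stats([f.params.dH for f in kept])
    ds_m, ds_s = stats([f.params.dS for f in kept])
    dg_m, dg_s = stats([f.dg37 for f in kept])
    tm_m, tm_s = stats([f.tm_fit for f in kept])
    return ReplicateSummary(dh_m, dh_s, ds_m, ds_s, dg_m, dg_s, tm_m, tm_s,
                            n_replicates=len(kept), n_excluded=n_excluded,
                            label=label)


# ---------------------------------------------------------------------------
# extinction coefficients and strand concentration


def _load_extinction_table():
    mono, dimer = {}, {}
    text = (resources.files("srmotif.data") / "extinction_nn_260.tsv"
            ).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, key, eps = line.split("\t")
        (mono if kind == "mono" else dimer)[key] = float(eps)
    return mono, dimer


_EPS_MONO, _EPS_DIMER = _load_extinction_table()


def extinction_coefficient(sequence: str) -> float:
    """Single-strand molar extinction coefficient at 260 nm, M^-1 cm^-1.

    Nearest-neighbour formula over the bundled literature table:
    ``eps = sum_i 2*eps_dimer(i, i+1) - sum_{i=2}^{n-1} eps_mono(i)``.
    A length-1 sequence returns its nucleoside value.  For a duplex, sum
    the two strand values.
    """
    seq = sequence.upper().replace("T", "U")
    for i, base in enumerate(seq):
        if base not in _EPS_MONO:
            raise ValueError("invalid RNA base %r at position %d in %r"
                             % (base, i + 1, sequence))
    if len(seq) == 0:
        raise ValueError("empty sequence")
    if len(seq) == 1:
        return _EPS_MONO[seq]
    dimers = sum(2.0 * _EPS_DIMER[seq[i:i + 2]] for i in range(len(seq) - 1))
    monos = sum(_EPS_MONO[b] for b in seq[1:-1])
    return dimers - monos


def concentration_from_absorbance(a90: float, epsilon: float,
                                  path_cm: float = 1.0) -> float:
    """Beer-Lambert strand concentration (mol/L) from 90 degC absorbance."""
    if epsilon <= 0:
        raise ValueError("extinction coefficient must be positive; got %g"
                         % epsilon)
    if path_cm <= 0:
        raise ValueError("path length must be positive; got %g" % path_cm)
    if a90 < 0:
        raise ValueError("absorbance must be nonnegative; got %g" % a90)
    return a90 / (epsilon * path_cm)


# ---------------------------------------------------------------------------
# plain-text formats


def write_melting_curve(curve: MeltingCurve, path=None) -> str:
    """Serialise a curve to the two-column CSV dialect with '#' metadata.

    Deterministic formatting: identical inputs produce identical bytes.
    """
    buf = io.StringIO()
    buf.write("# label: %s\n" % curve.label)
    buf.write("# wavelength_nm: %g\n" % curve.wavelength)
    buf.write("# ct_molar: %.10g\n" % curve.c_total)
    buf.write("temperature_c,absorbance\n")
    for t, a in zip(curve.temperatures, curve.absorbances):
        buf.write("%.4f,%.8f\n" % (t, a))
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def read_melting_curve(source) -> MeltingCurve:
    """Parse the CSV dialect written by :func:`write_melting_curve`."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
        name = str(source)
    else:
        text = str(source)
        name = "<string>"
    meta = {}
    temps, absorb = [], []
    header_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            continue
        if not header_seen:
            if line.lower().replace(" ", "") != "temperature_c,absorbance":
                raise ValueError(
                    "%s:%d: expected header 'temperature_c,absorbance', "
                    "got %r" % (name, lineno, line))
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ValueError("%s:%d: malformed data row %r"
                             % (name, lineno, line))
        temps.append(float(parts[0]))
        absorb.append(float(parts[1]))
    if not header_seen or not temps:
        raise ValueError("%s: no melting-curve data found" % name)
    if "ct_molar" not in meta:
        raise ValueError("%s: missing required metadata key 'ct_molar'" % name)
    return MeltingCurve(
        temperatures=np.array(temps), absorbances=np.array(absorb),
        c_total=float(meta["ct_molar"]),
        wavelength=float(meta.get("wavelength_nm", 260)),
        label=meta.get("label", ""))


def write_fit_report(fits: Iterable[FitResult], path=None) -> str:
    """One TSV row per fitted curve with the headline parameters."""
    lines = ["label\tdH_kcal\tdS_eu\tdG37_kcal\ttm_c\tr2\tconverged"]
    for f in fits:
        lines.append("%s\t%.1f\t%.1f\t%.1f\t%.1f\t%.4f\t%s" % (
            f.label, f.params.dH, f.params.dS, f.dg37, f.tm_fit,
            f.r_squared, int(f.converged)))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
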