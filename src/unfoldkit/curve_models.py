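"""Fitting of pH, chemical and thermal denaturation curves.

The measured spectroscopic property X (an ellipticity, a fluorescence
intensity, or the spectral mass center) is modeled as the
population-weighted sum of the values for the two species present:

* pH titrations follow a Hill-type mixing of the protonated (acidic)
  and deprotonated (basic) species,
  ``X = (Xa + Xb 10^{n(pH - pKa)}) / (1 + 10^{n(pH - pKa)})``;
* chemical (denaturant) curves follow a two-state Boltzmann sigmoid with
  the linear extrapolation model, ``dG = m ([D]_1/2 - [D])``;
* thermal curves follow the same sigmoid with the Gibbs-Helmholtz dG(T).

Native/denatured baselines are linear in the abscissa.  Because the
underlying experiments on small marginally stable domains are frequently
irreversible, every fit result carries an "apparent" caveat: the fitted
midpoints and slopes describe the curve, not an equilibrium free energy,
and no dG of folding is derived from them.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

from .constants import R_GAS, celsius_to_kelvin
from .datatypes import DenaturationCurve, FitError, SpectralTrace
from .state_models import _two_state_seeds

__all__ = [
    "spectral_center",
    "hill_eval",
    "lem_gibbs",
    "chemical_eval",
    "thermal_gibbs",
    "thermal_eval",
    "TitrationFit",
    "ChemicalFit",
    "ThermalFit",
    "fit_titration",
    "fit_chemical",
    "fit_thermal",
]

IRREVERSIBILITY_CAVEAT = (
    "apparent parameters: denaturation assumed reversible by the model but "
    "typically irreversible in practice; no Gibbs energy is reported"
)


def spectral_center(trace: SpectralTrace) -> float:
    """Intensity-weighted mean reciprocal emission wavelength, in 1/um.

    <lambda> = (sum_i I_i / lambda_i) / (sum_i I_i), an intensive summary
    of a fluorescence spectrum (invariant under intensity scaling).
    """
    total = trace.intensities.sum()
    if total <= 0:
        raise ValueError("spectrum has no intensity")
    inv_nm = float((trace.intensities / trace.wavelengths).sum() / total)
    return inv_nm * 1000.0  # 1/nm -> 1/um


# ---------------------------------------------------------------------------
# model evaluations
# ---------------------------------------------------------------------------

def hill_eval(pH, pKa: float, n: float, Xa: float, Xb: float):
    """Hill titration of a spectroscopic property between two species."""
    pH = np.asarray(pH, dtype=float)
    r = 10.0 ** (n * (pH - pKa))
    return (Xa + Xb * r) / (1.0 + r)


def lem_gibbs(m: float, D_half: float, D):
    """Linear extrapolation model: dG = m ([D]_1/2 - [D]), kcal/mol."""
    return m * (D_half - np.asarray(D, dtype=float))


def _boltzmann_mix(XN, XD, dG, T_K):
    """Two-state sigmoid: X = (XN + XD exp(-dG/RT)) / (1 + exp(-dG/RT))."""
    k = np.exp(-dG / (R_GAS * T_K))
    return (XN + XD * k) / (1.0 + k)


def chemical_eval(D, m: float, D_half: float, XN, XD, T_K: float):
    """Two-state signal at denaturant concentration D (baselines already evaluated)."""
    return _boltzmann_mix(XN, XD, lem_gibbs(m, D_half, D), T_K)


def thermal_gibbs(T_K, Tm_C: float, dHm: float, dCp: float = 0.0):
    """dG(T) = dHm (1 - T/Tm) - dCp [(Tm - T) + T ln(T/Tm)], T in K."""
    T_K = np.asarray(T_K, dtype=float)
    Tm = celsius_to_kelvin(Tm_C)
    return dHm * (1.0 - T_K / Tm) - dCp * ((Tm - T_K) + T_K * np.log(T_K / Tm))


def thermal_eval(T_C, Tm_C: float, dHm: float, dCp: float, XN, XD):
    """Two-state thermal signal at temperature T (deg C), van't Hoff dHm."""
    T_K = celsius_to_kelvin(np.asarray(T_C, dtype=float))
    return _boltzmann_mix(XN, XD, thermal_gibbs(T_K, Tm_C, dHm, dCp), T_K)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

@dataclass
class TitrationFit:
    pKa: float
    n: float
    Xa: float
    Xb: float
    stderr: dict[str, float | None]
    success: bool
    message: str = ""
    caveat: str = IRREVERSIBILITY_CAVEAT


@dataclass
class ChemicalFit:
    m: float                      # kcal mol^-1 M^-1
    D_half: float                 # M
    XN: tuple[float, float]       # (intercept, slope) vs [D]
    XD: tuple[float, float]
    temperature_K: float
    stderr: dict[str, float | None]
    success: bool
    message: str = ""
    caveat: str = IRREVERSIBILITY_CAVEAT


@dataclass
class ThermalFit:
    Tm: float                     # deg C
    dHm: float                    # kcal/mol, van't Hoff
    dCp: float                    # kcal/(mol K)
    XN: tuple[float, float]       # (intercept, slope) vs T in deg C
    XD: tuple[float, float]
    stderr: dict[str, float | None]
    success: bool
    message: str = ""
    caveat: str = IRREVERSIBILITY_CAVEAT


# ---------------------------------------------------------------------------
# fitters (Levenberg-Marquardt throughout)
# ---------------------------------------------------------------------------

def fit_titration(curve: DenaturationCurve) -> TitrationFit:
    """Nonlinear least-squares Hill fit of a pH titration curve."""
    if curve.axis_kind != "pH":
        raise ValueError("titration fits need a pH curve")
    x, y = curve.x, curve.signal
    if len(x) < 6:
        raise FitError("need at least 6 points spanning the transition")
    if np.ptp(y) == 0:
        raise FitError("constant signal: titration parameters unidentifiable")

    mid, (a_lo, _, a_hi, _) = _two_state_seeds(x, y)
    params = lmfit.Parameters()
    params.add("pka", value=mid, min=x[0] - 3, max=x[-1] + 3)
    params.add("n", value=1.0, min=1e-3, max=10.0)
    params.add("xa", value=float(y[0]))
    params.add("xb", value=float(y[-1]))

    def residual(p):
        return hill_eval(x, p["pka"].value, p["n"].value, p["xa"].value, p["xb"].value) - y

    result = lmfit.minimize(residual, params, method="leastsq")
    p = result.params
    success = bool(result.success)
    message = result.message if isinstance(result.message, str) else ""
    if success and not (x[0] - 1 <= p["pka"].value <= x[-1] + 1):
        success = False
        message = "fitted pKa outside the measured pH range"
    return TitrationFit(
        pKa=float(p["pka"].value), n=float(p["n"].value),
        Xa=float(p["xa"].value), Xb=float(p["xb"].value),
        stderr={k: p[k].stderr for k in ("pka", "n", "xa", "xb")},
        success=success, message=message)


def _flag_sigmoid_quality(x, residuals, midpoint, amplitude):
    """Shared post-fit sanity checks for the two-state sigmoid fitters."""
    resid_sd = float(np.std(residuals))
    if not (x[0] <= midpoint <= x[-1]):
        return False, "fitted midpoint outside the measured range"
    if amplitude <= max(5.0 * resid_sd, 1e-12 * max(np.ptp(x), 1.0)):
        return False, "no resolvable sigmoidal transition (amplitude within noise)"
    return True, ""


def fit_chemical(curve: DenaturationCurve) -> ChemicalFit:
    """Linear-extrapolation-model fit of a denaturant curve with sloped baselines."""
    if curve.axis_kind != "denaturant_M":
        raise ValueError("chemical fits need a denaturant_M curve")
    if curve.temperature_K is None:
        raise ValueError("chemical curves need temperature_K for the Boltzmann factor")
    x, y = curve.x, curve.signal
    if len(x) < 8:
        raise FitError("too few points for a chemical denaturation fit")
    if np.ptp(y) == 0:
        raise FitError("constant signal: chemical fit unidentifiable")
    T_K = float(curve.temperature_K)

    mid, (an, bn, ad, bd) = _two_state_seeds(x, y)
    params = lmfit.Parameters()
    params.add("m", value=2.0, min=1e-3, max=50.0)
    params.add("dhalf", value=mid, min=x[0] - 2, max=x[-1] + 2)
    for name, val in (("an", an), ("bn", bn), ("ad", ad), ("bd", bd)):
        params.add(name, value=val)

    def residual(p):
        xn = p["an"].value + p["bn"].value * x
        xd = p["ad"].value + p["bd"].value * x
        return chemical_eval(x, p["m"].value, p["dhalf"].value, xn, xd, T_K) - y

    result = lmfit.minimize(residual, params, method="leastsq")
    p = result.params
    dhalf = float(p["dhalf"].value)
    amp = abs((p["ad"].value + p["bd"].value * dhalf) - (p["an"].value + p["bn"].value * dhalf))
    success, message = _flag_sigmoid_quality(x, result.residual, dhalf, amp)
    if not result.success:
        success, message = False, str(result.message)
    return ChemicalFit(
        m=float(p["m"].value), D_half=dhalf,
        XN=(float(p["an"].value), float(p["bn"].value)),
        XD=(float(p["ad"].value), float(p["bd"].value)),
        temperature_K=T_K,
        stderr={k: p[k].stderr for k in ("m", "dhalf")},
        success=success, message=message)


def fit_thermal(curve: DenaturationCurve, fix_dcp: float | None = None) -> ThermalFit:
    """Gibbs-Helmholtz two-state fit of a thermal denaturation curve.

    ``dCp`` floats by default (the functional form places no restriction
    on it) but is weakly identified by a single irreversible curve; pass
    ``fix_dcp=0.0`` to pin it, which reduces dG(T) to the van't Hoff form.
    """
    if curve.axis_kind != "temperature_C":
        raise ValueError("thermal fits need a temperature_C curve")
    x, y = curve.x, curve.signal
    if len(x) < 8:
        raise FitError("too few points for a thermal fit")
    if np.ptp(y) == 0:
        raise FitError("constant signal: thermal fit unidentifiable")

    mid, (an, bn, ad, bd) = _two_state_seeds(x, y)
    params = lmfit.Parameters()
    params.add("tm", value=mid, min=x[0] - 30, max=x[-1] + 30)
    params.add("dhm", value=60.0, min=1.0)
    params.add("dcp", value=0.0 if fix_dcp is None else fix_dcp, vary=fix_dcp is None)
    for name, val in (("an", an), ("bn", bn), ("ad", ad), ("bd", bd)):
        params.add(name, value=val)

    def residual(p):
        xn = p["an"].value + p["bn"].value * x
        xd = p["ad"].value + p["bd"].value * x
        return thermal_eval(x, p["tm"].value, p["dhm"].value, p["dcp"].value, xn, xd) - y

    result = lmfit.minimize(residual, params, method="leastsq")
    p = result.params
    tm = float(p["tm"].value)
    amp = abs((p["ad"].value + p["bd"].value * tm) - (p["an"].value + p["bn"].value * tm))
    success, message = _flag_sigmoid_quality(x, result.residual, tm, amp)
    if not result.success:
        success, message = False, str(result.message)
    return ThermalFit(
        Tm=tm, dHm=float(p["dhm"].value), dCp=float(p["dcp"].value),
        XN=(float(p["an"].value), float(p["bn"].value)),
        XD=(float(p["ad"].value), float(p["bd"].value)),
        stderr={k: p[k].stderr for k in ("tm", "dhm", "dcp")},
        success=success, message=message)
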