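"""Equilibrium statistical-thermodynamic unfolding models.

Two model families are implemented:

* a two-state (single-transition) model for thermal-shift (thermofluor)
  traces, where the measured fluorescence is the population-weighted sum
  of linear native/unfolded baselines; and
* a two-transition model for DSC thermograms, in which two energetic
  domains unfold independently, giving the four-state partition function
  ``Q = 1 + K1 + K2 + K1*K2 = (1 + K1)(1 + K2)`` (states: native, two
  intermediates, unfolded).  A sequential three-state variant
  ``Q = 1 + K1 + K1*K2`` is provided for comparison; the two coincide
  when ``K2 << K1`` (widely separated transitions).

Per transition, the Gibbs energy follows the Gibbs-Helmholtz relation

    dG(T) = dH(Tm) (1 - T/Tm) - dCp [(Tm - T) + T ln(T/Tm)]

with ``K(T) = exp(-dG/RT)``.  The average excess enthalpy is
``<dH>(T) = R T^2 dlnQ/dT`` and the excess heat capacity its temperature
derivative, evaluated in closed form through the enthalpy-fluctuation
identity ``<dCp> = (<h^2> - <h>^2)/(R T^2) + <cp>`` over the state
ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.signal import find_peaks

from .constants import R_GAS, celsius_to_kelvin
from .datatypes import BaselineParams, FitError, DenaturationCurve, Thermogram, TransitionParams

__all__ = [
    "equilibrium_K",
    "gibbs_energy",
    "partition_two_transition",
    "partition_three_state",
    "StatePopulations",
    "populations",
    "average_excess_enthalpy",
    "excess_heat_capacity",
    "DscFit",
    "fit_dsc",
    "thermofluor_signal",
    "two_state_populations",
    "ThermofluorFit",
    "fit_thermofluor",
    "specific_unfolding_enthalpy",
    "subtract_progress_baseline",
]


# ---------------------------------------------------------------------------
# elementary thermodynamics
# ---------------------------------------------------------------------------

def gibbs_energy(params: TransitionParams, T):
    """Gibbs-Helmholtz unfolding free energy (kcal/mol) at temperature T (K)."""
    T = np.asarray(T, dtype=float)
    Tm = celsius_to_kelvin(params.Tm)
    dG = params.dH * (1.0 - T / Tm)
    if params.dCp != 0.0:
        dG = dG - params.dCp * ((Tm - T) + T * np.log(T / Tm))
    return dG


def transition_enthalpy(params: TransitionParams, T):
    """dH(T) = dH(Tm) + dCp (T - Tm), in kcal/mol (T in K)."""
    Tm = celsius_to_kelvin(params.Tm)
    return params.dH + params.dCp * (np.asarray(T, dtype=float) - Tm)


def equilibrium_K(params: TransitionParams, T):
    """Conformational equilibrium constant K(T) = exp(-dG/RT), T in K."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    return np.exp(-gibbs_energy(params, T) / (R_GAS * T))


def partition_two_transition(K1, K2):
    """Q = 1 + K1 + K2 + K1*K2 for two independent energetic domains."""
    K1 = np.asarray(K1, dtype=float)
    K2 = np.asarray(K2, dtype=float)
    return (1.0 + K1) * (1.0 + K2)


def partition_three_state(K1, K2):
    """Q = 1 + K1 + K1*K2 for the sequential three-state model N <-> I <-> U."""
    K1 = np.asarray(K1, dtype=float)
    K2 = np.asarray(K2, dtype=float)
    return 1.0 + K1 + K1 * K2


# ---------------------------------------------------------------------------
# state populations and ensemble averages
# ---------------------------------------------------------------------------

@dataclass
class StatePopulations:
    """Fractional state populations on a temperature grid (deg C)."""

    temperature: np.ndarray
    native: np.ndarray
    intermediate1: np.ndarray
    intermediate2: np.ndarray
    unfolded: np.ndarray


def _state_weights(transitions, T_K, model: str = "two_transition"):
    """Boltzmann weights, state enthalpies and state dCp on a kelvin grid.

    Returns (weights, enthalpies, heat_capacities), each a list of arrays,
    ordered native, intermediate(s), unfolded.
    """
    t1, t2 = transitions
    K1 = equilibrium_K(t1, T_K)
    K2 = equilibrium_K(t2, T_K)
    h1 = transition_enthalpy(t1, T_K)
    h2 = transition_enthalpy(t2, T_K)
    zero = np.zeros_like(K1)
    one = np.ones_like(K1)
    if model == "two_transition":
        weights = [one, K1, K2, K1 * K2]
        enthalpies = [zero, h1, h2, h1 + h2]
        cps = [0.0, t1.dCp, t2.dCp, t1.dCp + t2.dCp]
    elif model == "three_state":
        weights = [one, K1, K1 * K2]
        enthalpies = [zero, h1, h1 + h2]
        cps = [0.0, t1.dCp, t1.dCp + t2.dCp]
    else:
        raise ValueError(f"unknown model {model!r}")
    return weights, enthalpies, cps


def populations(transitions, grid_C, model: str = "two_transition") -> StatePopulations:
    """Normalized state populations of the DSC model on a Celsius grid.

    For the two-transition model the four states are native (1/Q),
    intermediate 1 (K1/Q), intermediate 2 (K2/Q) and unfolded (K1K2/Q).
    For the three-state model the single intermediate is reported in
    ``intermediate1`` and ``intermediate2`` is identically zero.
    """
    grid_C = np.asarray(grid_C, dtype=float)
    if grid_C.size >= 2 and not np.all(np.diff(grid_C) > 0):
        raise ValueError("temperature grid must be strictly increasing")
    T_K = celsius_to_kelvin(grid_C)
    weights, _, _ = _state_weights(transitions, T_K, model)
    Q = sum(weights)
    fracs = [w / Q for w in weights]
    if model == "three_state":
        fracs = [fracs[0], fracs[1], np.zeros_like(Q), fracs[2]]
    return StatePopulations(grid_C, *fracs)


def average_excess_enthalpy(transitions, T, model: str = "two_transition"):
    """<dH>(T) = R T^2 dlnQ/dT in kcal/mol (T in K).

    Expands to ``P1 dH1 + P2 dH2 + P12 (dH1 + dH2)`` for the
    two-transition model (native state is the enthalpy reference).
    """
    T_K = np.asarray(T, dtype=float)
    weights, enthalpies, _ = _state_weights(transitions, T_K, model)
    Q = sum(weights)
    return sum(w * h for w, h in zip(weights, enthalpies)) / Q


def excess_heat_capacity(transitions, grid_C, model: str = "two_transition") -> Thermogram:
    """Analytic excess molar heat capacity <dCp>(T) on a Celsius grid.

    Uses the fluctuation identity
    ``<dCp> = (<h^2> - <h>^2) / (R T^2) + sum_s P_s cp_s``,
    which is the exact temperature derivative of the average excess
    enthalpy for temperature-dependent state enthalpies.
    """
    grid_C = np.asarray(grid_C, dtype=float)
    if grid_C.size >= 2 and not np.all(np.diff(grid_C) > 0):
        raise ValueError("temperature grid must be strictly increasing")
    T_K = celsius_to_kelvin(grid_C)
    weights, enthalpies, cps = _state_weights(transitions, T_K, model)
    Q = sum(weights)
    probs = [w / Q for w in weights]
    mean_h = sum(p * h for p, h in zip(probs, enthalpies))
    mean_h2 = sum(p * h * h for p, h in zip(probs, enthalpies))
    mean_cp = sum(p * c for p, c in zip(probs, cps))
    cp = (mean_h2 - mean_h**2) / (R_GAS * T_K**2) + mean_cp
    return Thermogram(grid_C, cp)


# ---------------------------------------------------------------------------
# DSC fitting
# ---------------------------------------------------------------------------

@dataclass
class DscFit:
    """Result of a multi-transition DSC fit; transitions sorted by Tm."""

    transitions: tuple[TransitionParams, TransitionParams]
    model: str
    stderr: dict[str, float | None]
    success: bool
    message: str = ""
    redchi: float | None = None
    metadata: dict = field(default_factory=dict)

    def populations(self, grid_C) -> StatePopulations:
        return populations(self.transitions, grid_C, model=self.model)


def _dsc_initial_guess(thermogram: Thermogram):
    """Seed (Tm1, dH1, Tm2, dH2) from the two most prominent thermogram peaks.

    Enthalpy seeds use the two-state peak-height relation
    dH^2 ~= 4 R Tm^2 Cp_max.
    """
    t = thermogram.temperature
    cp = thermogram.excess_cp
    span = float(np.ptp(cp))
    idx, props = find_peaks(cp, prominence=0.05 * span if span > 0 else None)
    if idx.size >= 2:
        order = np.argsort(props["prominences"])[::-1][:2]
        picks = np.sort(idx[order])
    elif idx.size == 1:
        # single visible peak: split heuristically
        i = idx[0]
        picks = np.array([max(i - len(t) // 10, 0), min(i + len(t) // 10, len(t) - 1)])
    else:
        picks = np.array([len(t) // 3, 2 * len(t) // 3])
    seeds = []
    for i in picks:
        tm = float(t[i])
        cpmax = max(float(cp[i]), 1e-3)
        dh = 2.0 * celsius_to_kelvin(tm) * np.sqrt(R_GAS * cpmax)
        seeds.append((tm, dh))
    return seeds


def fit_dsc(thermogram: Thermogram, model: str = "two_transition",
            vary_dcp: bool = False) -> DscFit:
    """Fit a (baseline-subtracted) thermogram with the requested DSC model.

    Estimates (Tm1, dH1, Tm2, dH2) and, when ``vary_dcp`` is set, the
    per-transition heat-capacity increments.  The thermogram is expected
    to hold the excess heat capacity only (any progress baseline removed
    beforehand; see :func:`subtract_progress_baseline`).
    """
    if model not in ("two_transition", "three_state"):
        raise ValueError(f"unknown model {model!r}")
    t = thermogram.temperature
    cp = thermogram.excess_cp
    if len(t) < 8:
        raise FitError("too few points for a DSC fit")
    if np.ptp(cp) <= 0:
        raise FitError("flat thermogram: no transition to fit")

    (tm1, dh1), (tm2, dh2) = _dsc_initial_guess(thermogram)
    params = lmfit.Parameters()
    params.add("tm1", value=tm1, min=t[0] - 20, max=t[-1] + 20)
    params.add("dh1", value=dh1, min=1e-3)
    params.add("tm2", value=tm2, min=t[0] - 20, max=t[-1] + 20)
    params.add("dh2", value=dh2, min=1e-3)
    params.add("dcp1", value=0.0, vary=vary_dcp)
    params.add("dcp2", value=0.0, vary=vary_dcp)

    def residual(p):
        trs = (TransitionParams(p["tm1"].value, p["dh1"].value, p["dcp1"].value),
               TransitionParams(p["tm2"].value, p["dh2"].value, p["dcp2"].value))
        return excess_heat_capacity(trs, t, model=model).excess_cp - cp

    result = lmfit.minimize(residual, params, method="leastsq")
    p = result.params
    pairs = sorted([("1", p["tm1"].value, p["dh1"].value, p["dcp1"].value),
                    ("2", p["tm2"].value, p["dh2"].value, p["dcp2"].value)],
                   key=lambda item: item[1])
    transitions = tuple(TransitionParams(tm, dh, dcp) for _, tm, dh, dcp in pairs)
    stderr = {}
    for newlab, (oldlab, *_rest) in zip(("1", "2"), pairs):
        stderr[f"Tm{newlab}"] = p[f"tm{oldlab}"].stderr
        stderr[f"dH{newlab}"] = p[f"dh{oldlab}"].stderr
        stderr[f"dCp{newlab}"] = p[f"dcp{oldlab}"].stderr

    success = bool(result.success)
    message = result.message if isinstance(result.message, str) else ""
    if success and abs(transitions[0].Tm - transitions[1].Tm) < 0.5:
        success = False
        message = "parameter collapse: the two transitions are degenerate"
    return DscFit(transitions, model, stderr, success, message,
                  redchi=result.redchi,
                  metadata={"nfev": result.nfev, "ndata": result.ndata})


def subtract_progress_baseline(temperature, raw_cp, window: float = 0.2) -> Thermogram:
    """Remove a sigmoidal progress baseline from a raw thermogram.

    The baseline interpolates between linear pre- and post-transition
    segments (fitted on the terminal ``window`` fraction of points),
    weighted by the normalized integral of the signal itself (the
    unfolding progress), yielding the excess heat capacity.
    """
    t = np.asarray(temperature, dtype=float)
    cp = np.asarray(raw_cp, dtype=float)
    k = max(int(len(t) * window), 2)
    pre = np.polyfit(t[:k], cp[:k], 1)
    post = np.polyfit(t[-k:], cp[-k:], 1)
    lower = np.polyval(pre, t)
    upper = np.polyval(post, t)
    area = np.concatenate([[0.0], np.cumsum(np.diff(t) * 0.5 * ((cp - lower)[1:] + (cp - lower)[:-1]))])
    total = area[-1] if area[-1] != 0 else 1.0
    progress = np.clip(area / total, 0.0, 1.0)
    baseline = lower * (1 - progress) + upper * progress
    return Thermogram(t, cp - baseline)


# ---------------------------------------------------------------------------
# two-state thermofluor model
# ---------------------------------------------------------------------------

def two_state_populations(params: TransitionParams, T):
    """(P_N, P_U) of the two-state model at temperature T (K)."""
    K = equilibrium_K(params, T)
    return 1.0 / (1.0 + K), K / (1.0 + K)


def thermofluor_signal(params: TransitionParams, baselines: BaselineParams, T_C):
    """Observed fluorescence F(T) = P_N F_N(T) + P_U F_U(T).

    ``T_C`` is in Celsius; baselines are linear in Celsius temperature.
    """
    T_C = np.asarray(T_C, dtype=float)
    pn, pu = two_state_populations(params, celsius_to_kelvin(T_C))
    return pn * baselines.native(T_C) + pu * baselines.unfolded(T_C)


@dataclass
class ThermofluorFit:
    """Two-state fit of a thermal-shift trace."""

    Tm: float
    dH: float
    dCp: float
    baselines: BaselineParams
    stderr: dict[str, float | None]
    success: bool
    message: str = ""
    redchi: float | None = None


def _two_state_seeds(x, y):
    """Initial (midpoint, baselines) guesses shared by sigmoid-in-x fitters.

    The midpoint seed is the abscissa of the largest |numerical
    derivative| of the smoothed signal; baselines come from the terminal
    20% of points on each side.
    """
    k = max(int(len(x) * 0.2), 2)
    lo = np.polyfit(x[:k], y[:k], 1)
    hi = np.polyfit(x[-k:], y[-k:], 1)
    detrended = y - np.polyval(lo, x)
    deriv = np.gradient(detrended, x)
    mid = float(x[np.argmax(np.abs(deriv))])
    return mid, (lo[1], lo[0], hi[1], hi[0])


def fit_thermofluor(curve: DenaturationCurve, fix_dcp: float | None = 0.0) -> ThermofluorFit:
    """Fit the two-state thermofluor model to a temperature trace.

    ``fix_dcp=None`` lets the heat-capacity increment float; the default
    pins it at 0 kcal/(mol K), the usual choice when a single trace gives
    it no leverage.
    """
    if curve.axis_kind != "temperature_C":
        raise ValueError("thermofluor fits need a temperature_C curve")
    x, y = curve.x, curve.signal
    if len(x) < 8:
        raise FitError("too few points for a thermofluor fit")
    if np.ptp(y) == 0:
        raise FitError("flat trace: no transition to fit")

    tm0, (an, bn, au, bu) = _two_state_seeds(x, y)
    params = lmfit.Parameters()
    params.add("tm", value=tm0, min=x[0] - 30, max=x[-1] + 30)
    params.add("dh", value=80.0, min=1.0)
    params.add("dcp", value=0.0 if fix_dcp is None else fix_dcp, vary=fix_dcp is None)
    for name, val in (("an", an), ("bn", bn), ("au", au), ("bu", bu)):
        params.add(name, value=val)

    def residual(p):
        tr = TransitionParams(p["tm"].value, p["dh"].value, p["dcp"].value)
        bl = BaselineParams(p["an"].value, p["bn"].value, p["au"].value, p["bu"].value)
        return thermofluor_signal(tr, bl, x) - y

    result = lmfit.minimize(residual, params, method="leastsq")
    p = result.params
    success = bool(result.success)
    message = result.message if isinstance(result.message, str) else ""
    if success and not (x[0] - 5 <= p["tm"].value <= x[-1] + 5):
        success = False
        message = "fitted midpoint outside the measured temperature range"
    return ThermofluorFit(
        Tm=float(p["tm"].value), dH=float(p["dh"].value), dCp=float(p["dcp"].value),
        baselines=BaselineParams(p["an"].value, p["bn"].value, p["au"].value, p["bu"].value),
        stderr={k: p[k].stderr for k in ("tm", "dh", "dcp")},
        success=success, message=message, redchi=result.redchi)


def specific_unfolding_enthalpy(dH1: float, dH2: float, MW: float) -> float:
    """Total unfolding enthalpy per gram, (dH1 + dH2)/MW, in cal/g.

    ``dH`` values are kcal/mol, ``MW`` g/mol; useful for comparing the
    packing of different proteins on a mass-normalized scale.
    """
    if MW <= 0:
        raise ValueError("molecular weight must be positive")
    return 1000.0 * (dH1 + dH2) / MW
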