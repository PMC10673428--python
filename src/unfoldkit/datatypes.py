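"""Shared in-memory containers for measured and simulated curves.

These are deliberately thin: ordered observations plus enough metadata to
make downstream fitting self-describing.  Curves generated synthetically
carry their generating ("truth") parameters in ``metadata`` so recovery
tests can assert against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

AXIS_KINDS = ("pH", "denaturant_M", "temperature_C")


@dataclass
class DenaturationCurve:
    """Ordered (x, signal) observations of one denaturation experiment.

    Parameters
    ----------
    axis_kind:
        One of ``"pH"``, ``"denaturant_M"``, ``"temperature_C"``.
    x, signal:
        Equal-length arrays; ``x`` must be strictly monotone.
    temperature_K:
        Experiment temperature, required for chemical (denaturant) curves
        where it enters the Boltzmann factor.
    """

    axis_kind: str
    x: np.ndarray
    signal: np.ndarray
    temperature_K: float | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.axis_kind not in AXIS_KINDS:
            raise ValueError(f"unknown axis_kind {self.axis_kind!r}")
        if self.x.ndim != 1 or self.x.shape != self.signal.shape:
            raise ValueError("x and signal must be 1-D arrays of equal length")
        if self.x.size >= 2:
            dx = np.diff(self.x)
            if not (np.all(dx > 0) or np.all(dx < 0)):
                raise ValueError("x must be strictly monotone")

    def __len__(self) -> int:
        return self.x.size


@dataclass
class SpectralTrace:
    """A fluorescence emission spectrum: intensities on a wavelength grid (nm)."""

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must have equal length")
        if np.any(self.wavelengths <= 0):
            raise ValueError("wavelengths must be positive")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class TransitionParams:
    """One equilibrium unfolding transition: Tm (deg C), dH(Tm) and dCp.

    ``dH`` is the transition enthalpy at Tm in kcal/mol; ``dCp`` the
    unfolding heat-capacity increment in kcal/(mol K).
    """

    Tm: float
    dH: float
    dCp: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.Tm):
            raise ValueError("Tm must be finite")
        if self.dH < 0:
            raise ValueError("dH must be non-negative")


@dataclass
class BaselineParams:
    """Linear native/unfolded signal baselines: X_N = aN + bN*x, X_U = aU + bU*x."""

    aN: float
    bN: float
    aU: float
    bU: float

    def native(self, x):
        return self.aN + self.bN * np.asarray(x, dtype=float)

    def unfolded(self, x):
        return self.aU + self.bU * np.asarray(x, dtype=float)


@dataclass
class Thermogram:
    """Excess molar heat capacity on a temperature grid (deg C, kcal/(mol K))."""

    temperature: np.ndarray
    excess_cp: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.excess_cp = np.asarray(self.excess_cp, dtype=float)
        if self.temperature.shape != self.excess_cp.shape:
            raise ValueError("temperature and excess_cp must have equal length")
        if self.temperature.size >= 2 and not np.all(np.diff(self.temperature) > 0):
            raise ValueError("temperature grid must be strictly increasing")


@dataclass
class NoiseSpec:
    """Additive homoscedastic Gaussian noise for synthetic curves.

    ``sd=None`` asks the generator for its context default (1% of the
    clean-signal range for curves, 0.2 kcal/(mol K) for thermograms).
    Identical seeds produce bit-identical realizations.
    """

    sd: float | None = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd is not None and self.sd < 0:
            raise ValueError("noise sd must be non-negative")

    def sample(self, n: int, default_sd: float) -> np.ndarray:
        sd = default_sd if self.sd is None else self.sd
        if sd == 0:
            return np.zeros(n)
        rng = np.random.default_rng(self.seed)
        return rng.normal(0.0, sd, size=n)


class FitError(RuntimeError):
    """Raised when a curve is unusable for the requested fit (e.g. flat input)."""
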