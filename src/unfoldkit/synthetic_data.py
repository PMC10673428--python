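"""Synthetic inputs for every pipeline stage.

Curves are exact model evaluations (the same model code the fitters use)
plus additive homoscedastic Gaussian noise; the generating parameters are
stored in ``metadata["truth"]`` so recovery tests can assert against
them.  Structure fixtures are ideal poly-alanine backbones built from
internal coordinates with the NeRF construction; they are deterministic
and carry explicit covalent bonds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import BACKBONE_GEOMETRY as GEO
from .curve_models import chemical_eval, hill_eval
from .datatypes import (
    BaselineParams,
    DenaturationCurve,
    NoiseSpec,
    Thermogram,
    TransitionParams,
)
from .rigidity.structure import Atom, MolecularStructure
from .state_models import excess_heat_capacity, thermofluor_signal

__all__ = [
    "HelixFixtureSpec",
    "make_titration_curve",
    "make_thermogram",
    "make_thermofluor_trace",
    "make_chemical_curve",
    "make_helix_structure",
]

THERMOGRAM_DEFAULT_SD = 0.2   # kcal/(mol K)
CURVE_DEFAULT_SD_FRACTION = 0.01  # of the clean-signal range


def _check_grid(grid) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must not be empty")
    if grid.size >= 2 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    return grid


def _curve_noise(clean: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    return noise.sample(clean.size, CURVE_DEFAULT_SD_FRACTION * float(np.ptp(clean)))


def make_titration_curve(
    pKa: float, n: float, Xa: float, Xb: float, grid, noise: NoiseSpec
) -> DenaturationCurve:
    """Hill titration between the acidic (Xa) and basic (Xb) species."""
    grid = _check_grid(grid)
    clean = hill_eval(grid, pKa, n, Xa, Xb)
    return DenaturationCurve(
        "pH", grid, clean + _curve_noise(clean, noise),
        metadata={"truth": {"pKa": pKa, "n": n, "Xa": Xa, "Xb": Xb},
                  "noise_sd": noise.sd, "seed": noise.seed})


def make_thermogram(transitions, grid, noise: NoiseSpec) -> Thermogram:
    """Excess heat capacity of a one- or two-transition unfolding model.

    A single transition is padded with a zero-enthalpy partner, which is
    exactly inert in the heat-capacity expression.
    """
    grid = _check_grid(grid)
    transitions = list(transitions)
    if not 1 <= len(transitions) <= 2:
        raise ValueError("need one or two transitions")
    if len(transitions) == 1:
        transitions = transitions + [TransitionParams(float(np.mean(grid)), 0.0)]
    clean = excess_heat_capacity(transitions, grid).excess_cp
    noisy = clean + noise.sample(clean.size, THERMOGRAM_DEFAULT_SD)
    return Thermogram(
        grid, noisy,
        metadata={"truth": [{"Tm": t.Tm, "dH": t.dH, "dCp": t.dCp} for t in transitions],
                  "noise_sd": noise.sd, "seed": noise.seed})


def make_thermofluor_trace(
    params: TransitionParams, baselines: BaselineParams, grid, noise: NoiseSpec
) -> DenaturationCurve:
    """Two-state thermal trace with linear baselines (thermofluor model).

    Also serves as the generator for any two-state thermal denaturation
    signal (CD- or fluorescence-monitored): the model is identical.
    """
    grid = _check_grid(grid)
    clean = thermofluor_signal(params, baselines, grid)
    return DenaturationCurve(
        "temperature_C", grid, clean + _curve_noise(clean, noise),
        metadata={"truth": {"Tm": params.Tm, "dH": params.dH, "dCp": params.dCp,
                            "baselines": (baselines.aN, baselines.bN,
                                          baselines.aU, baselines.bU)},
                  "noise_sd": noise.sd, "seed": noise.seed})


def make_chemical_curve(
    m: float, D_half: float, XN: float, XD: float, grid, noise: NoiseSpec,
    temperature_K: float = 298.15,
) -> DenaturationCurve:
    """Two-state denaturant curve under the linear extrapolation model."""
    if m <= 0:
        raise ValueError("m must be positive")
    grid = _check_grid(grid)
    if np.any(grid < 0):
        raise ValueError("denaturant concentrations must be non-negative")
    clean = chemical_eval(grid, m, D_half, XN, XD, temperature_K)
    return DenaturationCurve(
        "denaturant_M", grid, clean + _curve_noise(clean, noise),
        temperature_K=temperature_K,
        metadata={"truth": {"m": m, "D_half": D_half, "XN": XN, "XD": XD,
                            "temperature_K": temperature_K},
                  "noise_sd": noise.sd, "seed": noise.seed})


# ---------------------------------------------------------------------------
# ideal helix fixture
# ---------------------------------------------------------------------------

@dataclass
class HelixFixtureSpec:
    """Poly-alanine backbone fixture; defaults give an ideal alpha helix."""

    n_residues: int = 12
    phi: float = -57.0
    psi: float = -47.0
    include_backbone_H: bool = True

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("need at least 4 residues")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, angle(b,c,d) and
    dihedral(a,b,c,d) as requested."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.sin(angle) * np.cos(torsion),
                  bond * np.sin(angle) * np.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def make_helix_structure(spec: HelixFixtureSpec) -> MolecularStructure:
    """Deterministic poly-alanine backbone (N, H, CA, CB, C, O) from ideal
    internal coordinates.

    The amide hydrogen sits on the in-plane bisector of the N->C(i-1) and
    N->CA directions (the first residue carries no amide H); CB completes
    a near-tetrahedral center.  Covalent bonds are recorded explicitly.
    """
    nres = spec.n_residues
    phi, psi, omega = spec.phi, spec.psi, GEO["omega"]

    # backbone heavy-atom trace
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([GEO["bond_N_CA"], 0.0, 0.0])]
    ang = np.deg2rad(GEO["angle_N_CA_C"])
    C = [CA[0] + GEO["bond_CA_C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, nres):
        N.append(_place(N[i - 1], CA[i - 1], C[i - 1],
                        GEO["bond_C_N"], GEO["angle_CA_C_N"], psi))
        CA.append(_place(CA[i - 1], C[i - 1], N[i],
                         GEO["bond_N_CA"], GEO["angle_C_N_CA"], omega))
        C.append(_place(C[i - 1], N[i], CA[i],
                        GEO["bond_CA_C"], GEO["angle_N_CA_C"], phi))

    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    index: dict[tuple[int, str], int] = {}

    def add(name: str, res: int, xyz: np.ndarray, element: str | None = None) -> int:
        idx = len(atoms)
        atoms.append(Atom(element or name[0], name, res, "ALA", "A", xyz))
        index[(res, name)] = idx
        return idx

    for i in range(nres):
        res = i + 1
        add("N", res, N[i])
        if spec.include_backbone_H and i > 0:
            h_dir = -_unit(_unit(C[i - 1] - N[i]) + _unit(CA[i] - N[i]))
            add("H", res, N[i] + GEO["bond_N_H"] * h_dir)
        add("CA", res, CA[i])
        # near-tetrahedral CB off the N-CA-C frame
        u1 = _unit(N[i] - CA[i])
        u2 = _unit(C[i] - CA[i])
        bisec = _unit(u1 + u2)
        perp = _unit(np.cross(u1, u2))
        a_coef = -np.cos(np.deg2rad(GEO["angle_N_CA_CB"])) / np.dot(u1, bisec)
        a_coef = np.clip(a_coef, -1.0, 1.0)
        b_coef = np.sqrt(max(1.0 - a_coef**2, 0.0))
        cb_dir = _unit(-a_coef * bisec + b_coef * perp)
        add("CB", res, CA[i] + GEO["bond_CA_CB"] * cb_dir, element="C")
        add("C", res, C[i])
        if i < nres - 1:
            o_tor = psi + 180.0
        else:
            o_tor = 180.0  # trans to the chain direction at the C terminus
        add("O", res, _place(N[i], CA[i], C[i],
                             GEO["bond_C_O"], GEO["angle_CA_C_O"], o_tor))

    for i in range(nres):
        res = i + 1
        if (res, "H") in index:
            bonds.append((index[(res, "N")], index[(res, "H")]))
        bonds.append((index[(res, "N")], index[(res, "CA")]))
        bonds.append((index[(res, "CA")], index[(res, "CB")]))
        bonds.append((index[(res, "CA")], index[(res, "C")]))
        bonds.append((index[(res, "C")], index[(res, "O")]))
        if i < nres - 1:
            bonds.append((index[(res, "C")], index[(res + 1, "N")]))
    return MolecularStructure(atoms, bonds)
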