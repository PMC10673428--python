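"""Geometric detection of non-covalent constraints.

Hydrogen bonds are scored with a Mayo-style distance/angle potential

    E = V0 [5 (R0/R)^12 - 6 (R0/R)^10] cos^2(theta) exp(-(pi-theta)^6) cos^2(phi)

where R is the donor-acceptor distance (optimum R0 = 2.8 A, well depth
scale V0 = 8 kcal/mol), theta the donor-H-acceptor angle and phi the
H-acceptor-antecedent angle.  Candidates must satisfy R <= 3.6 A and
theta >= 90 deg; only meaningfully favorable bonds (E below a small
negative threshold) are kept.

Hydrophobic tethers join carbon/sulfur atoms from residues at least two
apart in sequence that sit within the sum of their united-atom van der
Waals radii plus 0.25 A.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from ..constants import (
    HB_DA_CUTOFF,
    HB_MIN_STRENGTH,
    HB_R0,
    HB_THETA_MIN,
    HB_V0,
    HYDROPHOBIC_MIN_SEQ_SEP,
    HYDROPHOBIC_SLACK,
    VDW_RADII,
)
from .structure import MolecularStructure


@dataclass
class HydrogenBond:
    """Indices refer to atoms of the source structure; energy in kcal/mol."""

    donor: int
    hydrogen: int
    acceptor: int
    energy: float

    def __post_init__(self) -> None:
        if self.energy > 0:
            raise ValueError("retained hydrogen bonds must have favorable (<= 0) energy")


def hbond_energy(r_da: float, theta: float, phi: float) -> float:
    """Mayo-style hydrogen-bond energy (kcal/mol); angles in radians."""
    x = HB_R0 / r_da
    radial = 5.0 * x**12 - 6.0 * x**10
    angular = np.cos(theta) ** 2 * np.exp(-((np.pi - theta) ** 6)) * np.cos(phi) ** 2
    return float(HB_V0 * radial * angular)


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in radians."""
    u = a - b
    v = c - b
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosv, -1.0, 1.0)))


def _bond_graph_distances(structure: MolecularStructure, source: int, limit: int) -> dict[int, int]:
    """Covalent-graph BFS distances from ``source`` up to ``limit`` bonds."""
    adj: dict[int, list[int]] = {}
    for i, j in structure.bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        if dist[u] >= limit:
            continue
        for v in adj.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def detect_hbonds(structure: MolecularStructure) -> list[HydrogenBond]:
    """Geometric hydrogen-bond candidates scored by the Mayo-style potential.

    Donors are N/O atoms with a covalently attached hydrogen; acceptors
    are O (and N without attached H) atoms.  Donor-acceptor pairs closer
    than four covalent bonds are excluded so that intra-residue and
    peptide-unit geometry never scores.  Bonds are returned sorted from
    weakest (least favorable) to strongest.
    """
    adj: dict[int, list[int]] = {}
    for i, j in structure.bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)

    donors = []  # (donor_idx, hydrogen_idx)
    for i, atom in enumerate(structure.atoms):
        if atom.element in ("N", "O"):
            for j in adj.get(i, ()):
                if structure.atoms[j].element == "H":
                    donors.append((i, j))
    acceptors = []
    for i, atom in enumerate(structure.atoms):
        if atom.element == "O":
            acceptors.append(i)
        elif atom.element == "N" and not any(
            structure.atoms[j].element == "H" for j in adj.get(i, ())
        ):
            acceptors.append(i)

    bonds: list[HydrogenBond] = []
    theta_min = np.deg2rad(HB_THETA_MIN)
    for d_idx, h_idx in donors:
        excluded = _bond_graph_distances(structure, d_idx, limit=3)
        d_pos = structure.atoms[d_idx].xyz
        h_pos = structure.atoms[h_idx].xyz
        for a_idx in acceptors:
            if a_idx in excluded:
                continue
            a_pos = structure.atoms[a_idx].xyz
            r_da = float(np.linalg.norm(a_pos - d_pos))
            if r_da > HB_DA_CUTOFF or r_da < 1e-6:
                continue
            theta = _angle(d_pos, h_pos, a_pos)
            if theta < theta_min:
                continue
            antecedents = [j for j in adj.get(a_idx, ()) if structure.atoms[j].element != "H"]
            if antecedents:
                phi = _angle(h_pos, a_pos, structure.atoms[antecedents[0]].xyz)
            else:
                phi = np.pi  # free acceptor: no antecedent penalty
            energy = hbond_energy(r_da, theta, phi)
            if energy <= -HB_MIN_STRENGTH:
                bonds.append(HydrogenBond(d_idx, h_idx, a_idx, energy))
    bonds.sort(key=lambda b: b.energy, reverse=True)  # weakest first
    return bonds


def detect_tethers(structure: MolecularStructure) -> list[tuple[int, int]]:
    """Hydrophobic tethers: close C/S pairs from non-adjacent residues."""
    candidates = [
        (i, a) for i, a in enumerate(structure.atoms) if a.element in VDW_RADII
    ]
    tethers: list[tuple[int, int]] = []
    for ai in range(len(candidates)):
        i, atom_i = candidates[ai]
        for aj in range(ai + 1, len(candidates)):
            j, atom_j = candidates[aj]
            if abs(atom_i.res_index - atom_j.res_index) < HYDROPHOBIC_MIN_SEQ_SEP:
                continue
            cutoff = VDW_RADII[atom_i.element] + VDW_RADII[atom_j.element] + HYDROPHOBIC_SLACK
            if np.linalg.norm(atom_i.xyz - atom_j.xyz) <= cutoff:
                tethers.append((i, j))
    return tethers
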