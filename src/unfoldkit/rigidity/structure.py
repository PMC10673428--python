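"""Minimal molecular structure container for rigidity analysis.

Holds atoms (element, PDB-style name, 1-based residue index, chain,
coordinates in Angstrom) and an explicit covalent bond list.  When a
structure arrives without connectivity, bonds are inferred from covalent
radii; explicit CONECT-style records take precedence at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..constants import COVALENT_RADII, COVALENT_SLACK


@dataclass
class Atom:
    element: str
    name: str
    res_index: int      # 1-based
    res_name: str
    chain: str
    xyz: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name} has invalid coordinates")


@dataclass
class MolecularStructure:
    """A single-model, single-conformer structure with explicit bonds."""

    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bond ({i}, {j}) references invalid atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([a.res_index for a in self.atoms])

    def residues(self) -> list[int]:
        """Sorted distinct residue indices."""
        return sorted({a.res_index for a in self.atoms})

    def atom_index(self, res_index: int, name: str) -> int | None:
        for i, a in enumerate(self.atoms):
            if a.res_index == res_index and a.name == name:
                return i
        return None

    def with_bonds_inferred(self) -> "MolecularStructure":
        return MolecularStructure(self.atoms, infer_covalent_bonds(self.atoms))


def infer_covalent_bonds(atoms: list[Atom]) -> list[tuple[int, int]]:
    """Distance-based covalent bond inference from element covalent radii.

    A pair is bonded when closer than r_i + r_j + slack.  Unknown
    elements fall back to the carbon radius.
    """
    pos = np.array([a.xyz for a in atoms])
    radii = np.array([COVALENT_RADII.get(a.element, COVALENT_RADII["C"]) for a in atoms])
    bonds: list[tuple[int, int]] = []
    n = len(atoms)
    if n < 2:
        return bonds
    # O(n^2) is fine at fixture scale; cutoff matrix keeps it vectorized
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    cut = radii[:, None] + radii[None, :] + COVALENT_SLACK
    ii, jj = np.nonzero((d < cut) & (d > 1e-6))
    for i, j in zip(ii, jj):
        if i < j:
            bonds.append((int(i), int(j)))
    return bonds
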