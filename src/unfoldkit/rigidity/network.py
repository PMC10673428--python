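"""Body-and-bar constraint network assembly.

Each atom is a rigid body; constraints are typed multi-bar edges:
covalent bonds and hydrogen bonds contribute five bars (one residual
dihedral degree of freedom), hydrophobic tethers two.  At dilution
energy E only hydrogen bonds with |E_HB| >= E remain; covalent bonds
and tethers are never diluted.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..constants import BARS_COVALENT, BARS_HBOND, BARS_HYDROPHOBIC
from .interactions import HydrogenBond, detect_hbonds, detect_tethers
from .structure import MolecularStructure


@dataclass(frozen=True)
class ConstraintEdge:
    i: int
    j: int
    bars: int
    kind: str                  # "covalent" | "hydrogen_bond" | "hydrophobic"
    energy: float | None = None  # kcal/mol, hydrogen bonds only

    def __post_init__(self) -> None:
        if self.bars not in (BARS_HYDROPHOBIC, BARS_COVALENT):
            raise ValueError("bar multiplicity must be 2 or 5")


@dataclass
class ConstraintNetwork:
    n_bodies: int
    edges: list[ConstraintEdge]

    def __post_init__(self) -> None:
        for e in self.edges:
            if not (0 <= e.i < self.n_bodies and 0 <= e.j < self.n_bodies) or e.i == e.j:
                raise ValueError(f"edge ({e.i}, {e.j}) references invalid bodies")


def build_network(
    structure: MolecularStructure,
    E: float = 0.0,
    hbonds: list[HydrogenBond] | None = None,
    tethers: list[tuple[int, int]] | None = None,
) -> ConstraintNetwork:
    """Constraint network of ``structure`` at dilution energy E (kcal/mol).

    ``hbonds``/``tethers`` may be supplied to reuse detections across an
    energy sweep (the network is a deterministic function of structure
    and E either way).
    """
    if E < 0:
        raise ValueError("dilution energy must be non-negative")
    if hbonds is None:
        hbonds = detect_hbonds(structure)
    if tethers is None:
        tethers = detect_tethers(structure)
    edges = [ConstraintEdge(i, j, BARS_COVALENT, "covalent") for i, j in structure.bonds]
    for hb in hbonds:
        if abs(hb.energy) >= E:
            edges.append(
                ConstraintEdge(hb.donor, hb.acceptor, BARS_HBOND, "hydrogen_bond", hb.energy)
            )
    edges.extend(ConstraintEdge(i, j, BARS_HYDROPHOBIC, "hydrophobic") for i, j in tethers)
    return ConstraintNetwork(len(structure), edges)
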