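"""Reading and writing of curves (CSV/TSV) and structures (PDB).

Curves are two-column numeric tables (header optional, comma or
whitespace delimited).  Structures use single-model PDB; explicit CONECT
records override distance-based covalent bond inference.  Synthetic
curves are written with a JSON sidecar holding their generating
parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .datatypes import DenaturationCurve, Thermogram
from .rigidity.structure import Atom, MolecularStructure, infer_covalent_bonds

__all__ = [
    "read_curve",
    "write_curve",
    "read_thermogram",
    "write_thermogram",
    "read_structure",
    "write_structure",
]


def _read_two_columns(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None,
                     skip_blank_lines=True)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    df = df.iloc[:, :2]
    # drop a header row if the first row is non-numeric
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    out = df.apply(pd.to_numeric, errors="coerce")
    if out.isna().any().any():
        bad = df[out.isna().any(axis=1)].iloc[0].tolist()
        raise ValueError(f"{path}: non-numeric row {bad}")
    out.columns = ["x", "y"]
    return out.astype(float)


def read_curve(path, axis_kind: str, temperature_K: float | None = None) -> DenaturationCurve:
    """Load a two-column curve; validates numeric content and distinct x."""
    path = Path(path)
    df = _read_two_columns(path)
    if len(df) < 4:
        raise ValueError(f"{path}: need at least 4 points, found {len(df)}")
    dup = df["x"][df["x"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicated x value {dup.iloc[0]}")
    df = df.sort_values("x")
    return DenaturationCurve(axis_kind, df["x"].to_numpy(), df["y"].to_numpy(),
                             temperature_K=temperature_K,
                             metadata={"source": str(path)})


def write_curve(curve: DenaturationCurve, path) -> None:
    """Write a curve as (x, signal) CSV plus a JSON sidecar of its metadata."""
    path = Path(path)
    pd.DataFrame({"x": curve.x, "signal": curve.signal}).to_csv(path, index=False)
    sidecar = {"axis_kind": curve.axis_kind, "temperature_K": curve.temperature_K,
               **curve.metadata}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_thermogram(path) -> Thermogram:
    df = _read_two_columns(Path(path))
    df = df.sort_values("x")
    return Thermogram(df["x"].to_numpy(), df["y"].to_numpy(),
                      metadata={"source": str(path)})


def write_thermogram(tg: Thermogram, path) -> None:
    path = Path(path)
    pd.DataFrame({"temperature_C": tg.temperature, "excess_cp": tg.excess_cp}
                 ).to_csv(path, index=False)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(tg.metadata, indent=1))


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def _parse_conect(path: Path, serial_to_index: dict[int, int]) -> list[tuple[int, int]]:
    bonds: set[tuple[int, int]] = set()
    for line in path.read_text().splitlines():
        if not line.startswith("CONECT"):
            continue
        fields = [line[6:11]] + [line[k:k + 5] for k in range(11, len(line), 5)]
        serials = [int(f) for f in fields if f.strip()]
        if len(serials) < 2:
            continue
        a = serial_to_index.get(serials[0])
        for s in serials[1:]:
            b = serial_to_index.get(s)
            if a is not None and b is not None and a != b:
                bonds.add((min(a, b), max(a, b)))
    return sorted(bonds)


def read_structure(path) -> MolecularStructure:
    """Load a single-model PDB file.

    Multi-model files, alternate locations and insertion codes are
    rejected; CONECT records, when present, define the covalent bonds,
    otherwise bonds are inferred from covalent radii.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    st = gemmi.read_structure(str(path))
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise ValueError(f"{path}: no atoms found")
    if len(st) > 1:
        raise ValueError(f"{path}: multi-model files are not supported")
    atoms: list[Atom] = []
    serial_to_index: dict[int, int] = {}
    for chain in st[0]:
        for res in chain:
            if res.seqid.icode not in (" ", ""):
                raise ValueError(f"{path}: insertion codes are not supported")
            for at in res:
                if at.altloc not in ("", "\x00"):
                    raise ValueError(f"{path}: alternate locations are not supported")
                serial_to_index[at.serial] = len(atoms)
                atoms.append(Atom(
                    element=at.element.name.upper(),
                    name=at.name,
                    res_index=res.seqid.num,
                    res_name=res.name,
                    chain=chain.name,
                    xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=float(at.occ),
                    bfactor=float(at.b_iso),
                ))
    bonds = _parse_conect(path, serial_to_index)
    if not bonds:
        bonds = infer_covalent_bonds(atoms)
    return MolecularStructure(atoms, bonds)


def write_structure(structure: MolecularStructure, path, conect: bool = False) -> None:
    """Write a minimal single-model PDB (1-based serials, %.3f coordinates)."""
    st = gemmi.Structure()
    st.name = "unfoldkit"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    serial = 0
    for atom in structure.atoms:
        chain = chains.get(atom.chain)
        if chain is None:
            chain = gemmi.Chain(atom.chain)
            chains[atom.chain] = chain
            model.add_chain(chain)
            chain = model[-1]
            chains[atom.chain] = chain
        if len(chain) == 0 or chain[-1].seqid.num != atom.res_index:
            res = gemmi.Residue()
            res.name = atom.res_name
            res.seqid = gemmi.SeqId(atom.res_index, " ")
            chain.add_residue(res)
        res = chain[-1]
        at = gemmi.Atom()
        at.name = atom.name
        at.element = gemmi.Element(atom.element)
        at.pos = gemmi.Position(*atom.xyz)
        at.occ = atom.occupancy
        at.b_iso = atom.bfactor
        serial += 1
        at.serial = serial
        res.add_atom(at)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
    if conect and structure.bonds:
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip() != "END"]
        for i, j in structure.bonds:
            lines.append(f"CONECT{i + 1:>5d}{j + 1:>5d}")
        lines.append("END")
        Path(path).write_text("\n".join(lines) + "\n")
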