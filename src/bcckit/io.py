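"""Readers and writers for SYBYL mol2, xyz, SDF V2000 and charge tables.

mol2 is the primary interchange format: atoms, bonds with SYBYL order
tokens (``1 2 3 ar am``), coordinates and an optional per-atom charge
column.  Formal charges ride in a ``@<TRIPOS>UNITY_ATOM_ATTR`` section so
ionic species survive a round trip.  All indices are 1-based on disk and
0-based in memory.
"""

from __future__ import annotations

import io as _io
import math
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np

from . import data
from .chem import Atom, Bond, Molecule, MoleculeError

__all__ = [
    "ParseError",
    "read_mol2",
    "write_mol2",
    "read_xyz",
    "read_sdf",
    "read_charge_table",
    "write_charge_table",
    "round_preserving_sum",
]

_MOL2_ORDER_IN = {
    "1": "single", "2": "double", "3": "triple",
    "ar": "aromatic", "am": "amide",
}
_MOL2_ORDER_OUT = {
    "single": "1", "double": "2", "triple": "3",
    "aromatic": "ar", "amide": "am",
}
_SYBYL_SUFFIX = {
    ("C", "aromatic"): "C.ar", ("N", "aromatic"): "N.ar",
    ("C", "triple"): "C.1", ("C", "double"): "C.2",
    ("N", "double"): "N.2", ("O", "double"): "O.2",
}


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def as_text(source: str | Path | TextIO) -> str:
    """Coerce a file object, path, or literal multi-line text to text."""
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, str) and "\n" in source:
        return source
    return Path(source).read_text()


_as_text = as_text


# ---------------------------------------------------------------------------
# mol2
# ---------------------------------------------------------------------------

def read_mol2(source: str | Path | TextIO, split: bool = False):
    """Parse a SYBYL mol2 file into a :class:`Molecule`.

    The file's charge column, when present and nonzero anywhere, is kept on
    ``Molecule.precharges``.  With ``split=True`` a multi-fragment structure
    is returned as a list of connected molecules instead of raising.
    """
    lines = _as_text(source).splitlines()
    sections: dict[str, list[tuple[int, str]]] = {}
    current: str | None = None
    mol_count = 0
    for ln_no, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@<TRIPOS>"):
            current = line[len("@<TRIPOS>"):].upper()
            if current == "MOLECULE":
                mol_count += 1
                if mol_count > 1:
                    break  # only the first record is read
            sections.setdefault(current, [])
            continue
        if current is not None:
            sections[current].append((ln_no, line))

    for required in ("MOLECULE", "ATOM"):
        if required not in sections:
            raise ParseError(f"missing @<TRIPOS>{required} section")
    mol_lines = sections["MOLECULE"]
    if not mol_lines:
        raise ParseError("empty MOLECULE section")
    name = mol_lines[0][1]

    atoms: list[Atom] = []
    coords: list[list[float]] = []
    charges: list[float] = []
    for ln_no, line in sections["ATOM"]:
        parts = line.split()
        if len(parts) < 6:
            raise ParseError(f"line {ln_no}: short ATOM record")
        try:
            x, y, z = (float(v) for v in parts[2:5])
        except ValueError as exc:
            raise ParseError(f"line {ln_no}: bad coordinate: {exc}") from None
        element = parts[5].split(".")[0].capitalize()
        try:
            atoms.append(Atom(len(atoms), element, 0, label=parts[1]))
        except MoleculeError as exc:
            raise ParseError(f"line {ln_no}: {exc}") from None
        coords.append([x, y, z])
        charges.append(float(parts[8]) if len(parts) > 8 else 0.0)

    bonds: list[Bond] = []
    for ln_no, line in sections.get("BOND", []):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"line {ln_no}: short BOND record")
        try:
            i, j = int(parts[1]) - 1, int(parts[2]) - 1
        except ValueError:
            raise ParseError(f"line {ln_no}: bad bond atom index") from None
        token = parts[3].lower()
        if token not in _MOL2_ORDER_IN:
            raise ParseError(f"line {ln_no}: unknown bond order {parts[3]!r}")
        if not (0 <= i < len(atoms)) or not (0 <= j < len(atoms)):
            raise ParseError(
                f"line {ln_no}: bond references nonexistent atom "
                f"{max(i, j) + 1}"
            )
        bonds.append(Bond(i, j, _MOL2_ORDER_IN[token]))

    formal = {k: 0 for k in range(len(atoms))}
    attr_lines = sections.get("UNITY_ATOM_ATTR", [])
    idx = 0
    while idx < len(attr_lines):
        ln_no, line = attr_lines[idx]
        parts = line.split()
        atom_id, n_attr = int(parts[0]) - 1, int(parts[1])
        for k in range(n_attr):
            idx += 1
            _, attr_line = attr_lines[idx]
            key, value = attr_line.split()
            if key == "charge":
                formal[atom_id] = int(value)
        idx += 1
    if any(formal.values()):
        atoms = [
            Atom(a.index, a.element, formal[a.index], a.label) for a in atoms
        ]

    pre = np.array(charges) if any(abs(c) > 0 for c in charges) else None

    def build(atom_list, bond_list, coord_arr, pre_arr) -> Molecule:
        try:
            return Molecule(name, atom_list, bond_list, [coord_arr], pre_arr)
        except MoleculeError as exc:
            raise ParseError(str(exc)) from None

    coord_arr = np.array(coords)
    if not split:
        return build(atoms, bonds, coord_arr, pre)

    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    g.add_edges_from((b.i, b.j) for b in bonds)
    out = []
    for comp in sorted(nx.connected_components(g), key=min):
        order = sorted(comp)
        remap = {old: new for new, old in enumerate(order)}
        sub_atoms = [
            Atom(remap[i], atoms[i].element, atoms[i].formal_charge,
                 atoms[i].label)
            for i in order
        ]
        sub_bonds = [
            Bond(remap[b.i], remap[b.j], b.order)
            for b in bonds if b.i in comp
        ]
        sub_pre = pre[order] if pre is not None else None
        out.append(build(sub_atoms, sub_bonds, coord_arr[order], sub_pre))
    return out


def round_preserving_sum(values: np.ndarray, target_sum: float,
                         decimals: int = 6) -> np.ndarray:
    """Round to ``decimals`` so the printed values sum exactly to target.

    Largest-remainder apportionment: floor everything at the chosen
    precision, then hand out the missing least-significant units to the
    entries with the largest fractional remainders (ties broken by index).
    """
    values = np.asarray(values, dtype=float)
    scale = 10 ** decimals
    target_units = round(target_sum * scale)
    if not math.isclose(target_units, target_sum * scale, abs_tol=1e-6):
        raise ValueError(
            f"target sum {target_sum} is not representable at {decimals} dp"
        )
    scaled = values * scale
    floors = np.floor(scaled).astype(np.int64)
    deficit = int(target_units - floors.sum())
    remainders = scaled - floors
    order = np.argsort(-remainders, kind="stable")
    out = floors.copy()
    if deficit >= 0:
        for k in range(deficit):
            out[order[k % len(values)]] += 1
    else:
        # floor overshot (can happen with exact-integer inputs): take back
        # units from the smallest remainders first
        for k in range(-deficit):
            out[order[::-1][k % len(values)]] -= 1
    return out / scale


def _sybyl_type(molecule: Molecule, i: int) -> str:
    elem = molecule.atoms[i].element
    orders = [b.order for b in molecule.bonds if i in (b.i, b.j)]
    for order in ("aromatic", "triple", "double"):
        if (elem, order) in _SYBYL_SUFFIX and order in orders:
            return _SYBYL_SUFFIX[(elem, order)]
    if elem in ("C", "N", "O", "S", "P"):
        return f"{elem}.3"
    return elem


def write_mol2(molecule: Molecule, charges: np.ndarray | None = None,
               conformer: int = 0) -> str:
    """Serialize to mol2 text.

    The charge column is rounded to 6 decimals with largest-remainder
    repair so the printed column sums exactly to the molecule's net charge.
    Without an explicit charge vector the molecule's attached precharges
    are used, else zeros.
    """
    n = molecule.n_atoms
    if charges is None:
        charges = (molecule.precharges if molecule.precharges is not None
                   else np.zeros(n))
    charges = np.asarray(charges, dtype=float)
    if charges.shape != (n,):
        raise ValueError(
            f"charge vector length {charges.shape} != atom count {n}"
        )
    printed = round_preserving_sum(charges, float(molecule.net_charge))
    coords = (molecule.conformers[conformer] if molecule.conformers
              else np.zeros((n, 3)))
    buf = _io.StringIO()
    w = buf.write
    w("@<TRIPOS>MOLECULE\n")
    w(f"{molecule.name}\n")
    w(f"{n} {len(molecule.bonds)} 1 0 0\n")
    w("SMALL\nUSER_CHARGES\n")
    w("@<TRIPOS>ATOM\n")
    counts: dict[str, int] = {}
    for i, atom in enumerate(molecule.atoms):
        counts[atom.element] = counts.get(atom.element, 0) + 1
        label = atom.label or f"{atom.element}{counts[atom.element]}"
        x, y, z = coords[i]
        w(f"{i + 1:>5} {label:<6} {x:>12.4f} {y:>12.4f} {z:>12.4f} "
          f"{_sybyl_type(molecule, i):<6} 1 MOL {printed[i]:>10.6f}\n")
    w("@<TRIPOS>BOND\n")
    for k, bond in enumerate(molecule.bonds):
        w(f"{k + 1:>5} {bond.i + 1:>5} {bond.j + 1:>5} "
          f"{_MOL2_ORDER_OUT[bond.order]:>4}\n")
    charged = [a for a in molecule.atoms if a.formal_charge != 0]
    if charged:
        w("@<TRIPOS>UNITY_ATOM_ATTR\n")
        for atom in charged:
            w(f"{atom.index + 1} 1\ncharge {atom.formal_charge}\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# xyz
# ---------------------------------------------------------------------------

def read_xyz(source: str | Path | TextIO,
             perceive_bonds: bool = True) -> Molecule:
    """Read a standard xyz file; optionally perceive single bonds.

    Perception assigns a single bond wherever the interatomic distance is
    below r_cov(i) + r_cov(j) + 0.4 A.  Bond orders are left single; fix
    them before atom typing if the chemistry needs multiple bonds.
    """
    lines = _as_text(source).splitlines()
    if not lines:
        raise ParseError("empty xyz input")
    try:
        declared = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError("line 1: expected atom count") from None
    body = [ln for ln in lines[2:2 + declared]]
    if len(body) < declared or any(not ln.strip() for ln in body):
        raise ParseError(
            f"declared {declared} atoms but found fewer coordinate lines"
        )
    name = lines[1].strip() if len(lines) > 1 else ""
    atoms: list[Atom] = []
    coords = np.zeros((declared, 3))
    radii = data.covalent_radii()
    for k, ln in enumerate(body):
        parts = ln.split()
        if len(parts) < 4:
            raise ParseError(f"line {k + 3}: short coordinate line")
        elem = parts[0].capitalize() if len(parts[0]) > 1 else parts[0].upper()
        if elem not in radii:
            raise ParseError(f"line {k + 3}: unknown element {parts[0]!r}")
        atoms.append(Atom(k, elem))
        coords[k] = [float(v) for v in parts[1:4]]
    bonds: list[Bond] = []
    if perceive_bonds:
        for i in range(declared):
            for j in range(i + 1, declared):
                cutoff = (radii[atoms[i].element] + radii[atoms[j].element]
                          + data.PERCEPTION_TOLERANCE)
                if np.linalg.norm(coords[i] - coords[j]) < cutoff:
                    bonds.append(Bond(i, j, "single"))
    return Molecule(name or "xyz", atoms, bonds, [coords],
                    require_connected=perceive_bonds)


# ---------------------------------------------------------------------------
# SDF (V2000, read only)
# ---------------------------------------------------------------------------

def read_sdf(source: str | Path | TextIO) -> Molecule:
    """Read the first record of an SDF/MOL V2000 file via RDKit."""
    try:
        from rdkit import Chem
    except ImportError as exc:  # optional extra
        raise ImportError(
            "SDF reading needs RDKit; install the 'sdf' extra"
        ) from exc

    text = _as_text(source)
    rdmol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
    if rdmol is None:
        raise ParseError("RDKit could not parse the MOL/SDF block")
    order_map = {
        Chem.BondType.SINGLE: "single", Chem.BondType.DOUBLE: "double",
        Chem.BondType.TRIPLE: "triple", Chem.BondType.AROMATIC: "aromatic",
    }
    atoms = [
        Atom(a.GetIdx(), a.GetSymbol(), a.GetFormalCharge())
        for a in rdmol.GetAtoms()
    ]
    bonds = []
    for b in rdmol.GetBonds():
        if b.GetBondType() not in order_map:
            raise ParseError(f"unsupported SDF bond type {b.GetBondType()}")
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                          order_map[b.GetBondType()]))
    conf = rdmol.GetConformer() if rdmol.GetNumConformers() else None
    coords = (np.array([list(conf.GetAtomPosition(i)) for i in range(len(atoms))])
              if conf is not None else np.zeros((len(atoms), 3)))
    name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else "sdf"
    return Molecule(name or "sdf", atoms, bonds, [coords])


# ---------------------------------------------------------------------------
# charge tables
# ---------------------------------------------------------------------------

def read_charge_table(source: str | Path | TextIO, n_atoms: int) -> np.ndarray:
    """Two-column text (1-based atom index, charge in e), '#' comments."""
    charges = np.full(n_atoms, np.nan)
    for ln_no, raw in enumerate(_as_text(source).splitlines(), start=1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ParseError(f"line {ln_no}: expected index and charge")
        idx = int(parts[0]) - 1
        if not 0 <= idx < n_atoms:
            raise ParseError(f"line {ln_no}: atom index {idx + 1} out of range")
        charges[idx] = float(parts[1])
    if np.isnan(charges).any():
        missing = int(np.flatnonzero(np.isnan(charges))[0]) + 1
        raise ParseError(f"no charge given for atom {missing}")
    return charges


def write_charge_table(charges: Iterable[float]) -> str:
    lines = ["# atom_index\tcharge_e"]
    for k, q in enumerate(charges, start=1):
        lines.append(f"{k}\t{q:.6f}")
    return "\n".join(lines) + "\n"
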