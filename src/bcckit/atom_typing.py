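"""BCC atom-type perception and canonical bond-type keys.

A bond-charge-correction table is indexed by *bond-type keys*: an ordered
pair of atom-type codes plus a bond class.  Keys are canonicalized by
sorting the two codes lexicographically; the *orientation* records whether
a concrete bond runs along or against that canonical direction, which is
what makes the correction antisymmetric (and forces b(alpha,alpha) = 0 for
same-type bonds).

The shipped default rule list is a structural stand-in: it draws the same
kinds of distinctions the AM1-BCC family draws, but the vocabulary and the
companion values are this package's own.  Real parameter tables can be
dropped in through the same file format.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TextIO

from . import data
from .chem import Molecule, ring_info

__all__ = [
    "TypingError",
    "AtomTypeRule",
    "BOND_CLASSES",
    "BondTypeKey",
    "load_rules",
    "default_rules",
    "assign_atom_types",
    "assign_bond_keys",
]

BOND_CLASSES = ("single", "double", "triple", "aromatic", "delocalized")


class TypingError(ValueError):
    """An atom could not be typed or a rule/table file is malformed."""


@dataclass(frozen=True)
class AtomTypeRule:
    """One ordered perception rule; all specified fields must match."""

    element: str
    type_code: str
    degree: int | None = None
    aromatic: bool | None = None
    ring_size: int | None = None
    neighbors: tuple[str, ...] = ()

    def matches(self, element: str, degree: int, aromatic: bool,
                ring_size: int, neighbor_elements: Sequence[str]) -> bool:
        if element != self.element:
            return False
        if self.degree is not None and degree != self.degree:
            return False
        if self.aromatic is not None and aromatic != self.aromatic:
            return False
        if self.ring_size is not None and ring_size != self.ring_size:
            return False
        if self.neighbors:
            have = Counter(neighbor_elements)
            need = Counter(self.neighbors)
            if any(have[el] < n for el, n in need.items()):
                return False
        return True


def _parse_optional_int(token: str) -> int | None:
    return None if token == "*" else int(token)


def load_rules(source: str | Path | TextIO) -> list[AtomTypeRule]:
    """Load an ordered rule file (element degree aromatic ring nbrs code)."""
    from .io import as_text

    text = as_text(source)
    rules: list[AtomTypeRule] = []
    for ln_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 6:
            raise TypingError(f"line {ln_no}: expected 6 fields, got {len(parts)}")
        element, degree, aromatic, ring, nbrs, code = parts
        rules.append(AtomTypeRule(
            element=element,
            type_code=code,
            degree=_parse_optional_int(degree),
            aromatic=None if aromatic == "*" else aromatic == "yes",
            ring_size=_parse_optional_int(ring),
            neighbors=() if nbrs == "*" else tuple(nbrs.split(",")),
        ))
    return rules


def default_rules() -> list[AtomTypeRule]:
    return load_rules(data.default_rules_text())


def assign_atom_types(molecule: Molecule,
                      rules: Sequence[AtomTypeRule] | None = None
                      ) -> list[str]:
    """First-match typing over the ordered rule list.

    Deterministic and independent of atom ordering: each atom is typed
    from its own local environment only.
    """
    if rules is None:
        rules = default_rules()
    ri = ring_info(molecule)
    adj = molecule.neighbors()
    elements = molecule.elements()
    types: list[str] = []
    for atom in molecule.atoms:
        i = atom.index
        nbr_elems = [elements[j] for j in adj[i]]
        for rule in rules:
            if rule.matches(atom.element, len(adj[i]), ri.aromatic[i],
                            ri.smallest_ring_size[i], nbr_elems):
                types.append(rule.type_code)
                break
        else:
            raise TypingError(
                f"no typing rule matches atom {i} ({atom.element}, "
                f"degree {len(adj[i])})"
            )
    return types


@dataclass(frozen=True)
class BondTypeKey:
    """Canonical (sorted) bond-type key with traversal orientation.

    ``orientation`` is +1 when the bond's first atom (``Bond.i``) carries
    ``type_a`` and -1 otherwise; a table value b for this key is added to
    the ``type_a`` end and subtracted from the ``type_b`` end.
    """

    type_a: str
    type_b: str
    bond_class: str
    orientation: int = 1

    def __post_init__(self) -> None:
        if self.type_a > self.type_b:
            raise TypingError("key not canonical: type_a > type_b")
        if self.bond_class not in BOND_CLASSES:
            raise TypingError(f"unknown bond class {self.bond_class!r}")
        if self.orientation not in (-1, 1):
            raise TypingError("orientation must be +1 or -1")

    @property
    def pair(self) -> tuple[str, str, str]:
        """Orientation-free identity of the key (table index)."""
        return (self.type_a, self.type_b, self.bond_class)

    @property
    def is_self_pair(self) -> bool:
        return self.type_a == self.type_b


_ORDER_TO_CLASS = {
    "single": "single", "amide": "single", "double": "double",
    "triple": "triple", "aromatic": "aromatic",
}


def _delocalized_bonds(molecule: Molecule) -> set[tuple[int, int]]:
    """Bonds treated as delocalized: carboxylate C-O and nitro N-O pairs."""
    adj = molecule.neighbors()
    elements = molecule.elements()
    charges = [a.formal_charge for a in molecule.atoms]
    out: set[tuple[int, int]] = set()
    for atom in molecule.atoms:
        i = atom.index
        o_nbrs = [j for j in adj[i] if elements[j] == "O" and len(adj[j]) == 1]
        if len(o_nbrs) != 2:
            continue
        orders = sorted(molecule.bond_order(i, j) for j in o_nbrs)
        if atom.element == "C":
            group_charge = sum(charges[j] for j in o_nbrs)
            if orders == ["double", "single"] and group_charge == -1:
                out.update((min(i, j), max(i, j)) for j in o_nbrs)
        elif atom.element == "N":
            # nitro: two terminal oxygens on one nitrogen
            out.update((min(i, j), max(i, j)) for j in o_nbrs)
    return out


def assign_bond_keys(molecule: Molecule,
                     atom_types: Sequence[str]) -> list[BondTypeKey]:
    """One canonical, oriented key per bond (in bond order)."""
    if len(atom_types) != molecule.n_atoms:
        raise TypingError("atom_types length mismatch")
    deloc = _delocalized_bonds(molecule)
    keys: list[BondTypeKey] = []
    for bond in molecule.bonds:
        cls = _ORDER_TO_CLASS[bond.order]
        if bond.key in deloc:
            cls = "delocalized"
        ti, tj = atom_types[bond.i], atom_types[bond.j]
        if ti <= tj:
            keys.append(BondTypeKey(ti, tj, cls, +1))
        else:
            keys.append(BondTypeKey(tj, ti, cls, -1))
    return keys
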