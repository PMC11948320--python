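"""Molecular data model and graph utilities.

A :class:`Molecule` is a light-weight chemical graph: atoms carry an element
symbol and an integer formal charge, bonds carry an order drawn from the
small vocabulary used by SYBYL mol2 files (single, double, triple, aromatic,
amide).  One or more conformer coordinate sets (in Angstrom) may be attached.

The graph utilities here — ring perception and topological-equivalence
partitioning — feed atom typing and symmetry-aware charge analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "SUPPORTED_ELEMENTS",
    "BOND_ORDERS",
    "Atom",
    "Bond",
    "Molecule",
    "EquivalencePartition",
    "RingInfo",
    "equivalence_classes",
    "automorphism_orbits",
    "ring_info",
]

#: Elements the toolkit supports out of the box (organic set + halogens).
SUPPORTED_ELEMENTS = frozenset(
    {"H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I"}
)

#: Bond order vocabulary.  ``am`` (amide) is kept distinct on input so mol2
#: round trips preserve it; typing folds it into the single class.
BOND_ORDERS = ("single", "double", "triple", "aromatic", "amide")

_STANDARD_VALENCE = {
    "H": 1, "C": 4, "N": 3, "O": 2, "S": 2, "P": 3,
    "F": 1, "Cl": 1, "Br": 1, "I": 1,
}


class MoleculeError(ValueError):
    """Raised for invalid molecular graphs or inconsistent inputs."""


@dataclass(frozen=True)
class Atom:
    """One atom: 0-based ``index``, element symbol, integer formal charge."""

    index: int
    element: str
    formal_charge: int = 0
    label: str | None = None

    def __post_init__(self) -> None:
        if self.element not in SUPPORTED_ELEMENTS:
            raise MoleculeError(f"unsupported element {self.element!r}")


@dataclass(frozen=True)
class Bond:
    """Undirected bond between atom indices ``i`` and ``j``."""

    i: int
    j: int
    order: str = "single"

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise MoleculeError(f"bond endpoints coincide (atom {self.i})")
        if self.order not in BOND_ORDERS:
            raise MoleculeError(f"unknown bond order {self.order!r}")

    @property
    def key(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


@dataclass
class Molecule:
    """Connected molecular graph with optional conformer coordinates.

    Parameters
    ----------
    name:
        Free-text identifier.
    atoms:
        Atoms in index order; ``atoms[k].index == k`` is enforced.
    bonds:
        Undirected bonds without duplicates.
    conformers:
        List of ``(n_atoms, 3)`` coordinate arrays in Angstrom.
    precharges:
        Optional per-atom charge column carried over from an input file
        (e.g. the mol2 charge field), in elementary-charge units.
    """

    name: str
    atoms: list[Atom]
    bonds: list[Bond]
    conformers: list[np.ndarray] = field(default_factory=list)
    precharges: np.ndarray | None = None
    #: disable the connected-graph invariant (e.g. xyz read without
    #: bond perception); most workflows should leave this True
    require_connected: bool = True

    def __post_init__(self) -> None:
        for k, atom in enumerate(self.atoms):
            if atom.index != k:
                raise MoleculeError(
                    f"atom at position {k} has index {atom.index}; "
                    "atoms must be listed in index order"
                )
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for bond in self.bonds:
            for end in (bond.i, bond.j):
                if not 0 <= end < n:
                    raise MoleculeError(
                        f"bond ({bond.i},{bond.j}) references missing atom {end}"
                    )
            if bond.key in seen:
                raise MoleculeError(f"duplicate bond {bond.key}")
            seen.add(bond.key)
        self.conformers = [
            self._check_coords(np.asarray(c, dtype=float)) for c in self.conformers
        ]
        if self.precharges is not None:
            self.precharges = np.asarray(self.precharges, dtype=float)
            if self.precharges.shape != (n,):
                raise MoleculeError("precharge column length mismatch")
        if self.require_connected and n > 1 and not nx.is_connected(self.graph()):
            raise MoleculeError(
                "molecule graph is not connected; split fragments explicitly"
            )

    def _check_coords(self, coords: np.ndarray) -> np.ndarray:
        if coords.shape != (len(self.atoms), 3):
            raise MoleculeError(
                f"conformer shape {coords.shape} does not match atom count "
                f"{len(self.atoms)}"
            )
        return coords

    # -- basic accessors -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def net_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def graph(self) -> nx.Graph:
        """NetworkX view with ``element`` node and ``order`` edge attributes."""
        g = nx.Graph()
        for atom in self.atoms:
            g.add_node(atom.index, element=atom.element,
                       formal_charge=atom.formal_charge)
        for bond in self.bonds:
            g.add_edge(bond.i, bond.j, order=bond.order)
        return g

    def neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for bond in self.bonds:
            adj[bond.i].append(bond.j)
            adj[bond.j].append(bond.i)
        return adj

    def degree(self, i: int) -> int:
        return sum(1 for b in self.bonds if i in (b.i, b.j))

    def bond_order(self, i: int, j: int) -> str | None:
        for b in self.bonds:
            if b.key == ((i, j) if i < j else (j, i)):
                return b.order
        return None

    def add_conformer(self, coords: np.ndarray) -> int:
        self.conformers.append(self._check_coords(np.asarray(coords, float)))
        return len(self.conformers) - 1

    def permuted(self, perm: list[int]) -> "Molecule":
        """Return a relabeled copy where new index ``perm[i]`` = old atom ``i``."""
        n = self.n_atoms
        inv = [0] * n
        for old, new in enumerate(perm):
            inv[new] = old
        atoms = [
            Atom(new, self.atoms[old].element, self.atoms[old].formal_charge,
                 self.atoms[old].label)
            for new, old in enumerate(inv)
        ]
        bonds = [Bond(perm[b.i], perm[b.j], b.order) for b in self.bonds]
        confs = [c[inv] for c in self.conformers]
        pre = self.precharges[inv] if self.precharges is not None else None
        return Molecule(self.name, atoms, bonds, confs, pre)


# ---------------------------------------------------------------------------
# Ring perception
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RingInfo:
    """Per-atom smallest-ring size (0 = acyclic atom) and aromatic flag."""

    smallest_ring_size: tuple[int, ...]
    aromatic: tuple[bool, ...]


def _smallest_cycle_through(g: nx.Graph, v: int) -> int:
    """Length of the smallest cycle containing node ``v`` (0 if none).

    For each edge (v, u), the smallest cycle using that edge is the shortest
    v-u path in the graph with the edge removed, plus the edge itself.
    """
    best = 0
    for u in list(g.neighbors(v)):
        g.remove_edge(v, u)
        try:
            d = nx.shortest_path_length(g, v, u)
            best = d + 1 if best == 0 else min(best, d + 1)
        except nx.NetworkXNoPath:
            pass
        finally:
            g.add_edge(v, u)
    return best


def ring_info(molecule: Molecule) -> RingInfo:
    """Smallest-ring sizes and aromatic flags per atom.

    An atom is flagged aromatic iff it lies on a cycle whose bonds are all of
    order ``aromatic`` — equivalently, it lies on a cycle of the subgraph
    restricted to aromatic bonds.
    """
    g = molecule.graph()
    sizes = [_smallest_cycle_through(g, v) for v in range(molecule.n_atoms)]
    ar = nx.Graph()
    ar.add_nodes_from(range(molecule.n_atoms))
    ar.add_edges_from(
        (b.i, b.j) for b in molecule.bonds if b.order == "aromatic"
    )
    aromatic = [_smallest_cycle_through(ar, v) > 0 for v in range(molecule.n_atoms)]
    return RingInfo(tuple(sizes), tuple(aromatic))


# ---------------------------------------------------------------------------
# Topological equivalence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquivalencePartition:
    """Partition of atoms into topological-equivalence classes.

    ``class_ids[i]`` is the class of atom ``i``.  Class ids are canonical:
    they are assigned by sorting the underlying refinement invariants, so two
    relabelings of the same molecule yield the same partition structure.
    """

    class_ids: tuple[int, ...]

    @property
    def n_classes(self) -> int:
        return len(set(self.class_ids))

    def members(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for i, c in enumerate(self.class_ids):
            out.setdefault(c, []).append(i)
        return out


def equivalence_classes(molecule: Molecule) -> EquivalencePartition:
    """Topological equivalence by iterative neighbourhood refinement.

    Starting from the invariant (element, degree, formal charge, aromatic
    flag), each round replaces an atom's label with (own label, sorted
    multiset of (bond order, neighbour label)) until a fixed point.  The
    result is deterministic and independent of atom ordering, and is never
    finer than the automorphism orbit partition (every invariant used is
    preserved by graph automorphisms).
    """
    ri = ring_info(molecule)
    adj = molecule.neighbors()
    order_of = {}
    for b in molecule.bonds:
        order_of[(b.i, b.j)] = b.order
        order_of[(b.j, b.i)] = b.order
    labels: list[tuple] = [
        (a.element, len(adj[a.index]), a.formal_charge, ri.aromatic[a.index],
         ri.smallest_ring_size[a.index])
        for a in molecule.atoms
    ]
    n_prev = -1
    while True:
        new = [
            (labels[i],
             tuple(sorted((order_of[(i, j)], labels[j]) for j in adj[i])))
            for i in range(molecule.n_atoms)
        ]
        n_now = len(set(new))
        if n_now == n_prev:
            break
        labels, n_prev = new, n_now
    canon = {lab: k for k, lab in enumerate(sorted(set(labels)))}
    return EquivalencePartition(tuple(canon[lab] for lab in labels))


def automorphism_orbits(molecule: Molecule) -> EquivalencePartition:
    """Exact automorphism orbits by brute-force permutation search.

    Exponential in atom count; intended for small molecules (a guard caps
    it at 30 atoms, and in practice it is only fast well below that).
    """
    n = molecule.n_atoms
    if n > 30:
        raise MoleculeError("automorphism_orbits capped at 30 atoms")
    elems = molecule.elements()
    charges = [a.formal_charge for a in molecule.atoms]
    edges = {}
    for b in molecule.bonds:
        edges[b.key] = b.order
    # Only permutations preserving (element, charge) can be automorphisms:
    # permute within those groups.
    groups: dict[tuple, list[int]] = {}
    for i in range(n):
        groups.setdefault((elems[i], charges[i]), []).append(i)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    keys = list(groups)
    for assignment in itertools.product(
        *[itertools.permutations(groups[k]) for k in keys]
    ):
        perm = [0] * n
        for k, images in zip(keys, assignment):
            for src, dst in zip(groups[k], images):
                perm[src] = dst
        ok = True
        for (i, j), order in edges.items():
            pi, pj = perm[i], perm[j]
            kk = (pi, pj) if pi < pj else (pj, pi)
            if edges.get(kk) != order:
                ok = False
                break
        if ok:
            # bijectivity + equal edge count make the forward check sufficient
            for i in range(n):
                union(i, perm[i])
    roots = sorted({find(i) for i in range(n)})
    remap = {r: k for k, r in enumerate(roots)}
    return EquivalencePartition(tuple(remap[find(i)] for i in range(n)))


def check_valences(molecule: Molecule) -> None:
    """Raise if any atom exceeds its standard valence (order-weighted)."""
    weight = {"single": 1, "double": 2, "triple": 3, "aromatic": 1.5, "amide": 1}
    total = [0.0] * molecule.n_atoms
    for b in molecule.bonds:
        total[b.i] += weight[b.order]
        total[b.j] += weight[b.order]
    for a in molecule.atoms:
        allowed = _STANDARD_VALENCE[a.element] + abs(a.formal_charge)
        if total[a.index] > allowed + 0.5:
            raise MoleculeError(
                f"atom {a.index} ({a.element}) exceeds valence "
                f"{allowed}: {total[a.index]}"
            )
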