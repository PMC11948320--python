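"""Discrete torsional-state enumeration and chain-conformer geometry.

Rotatable bonds of a chain molecule are described by a three-state rotamer
alphabet — trans (180 deg), gauche+ (60 deg), gauche- (-60 deg).  Two state
vectors describe the same physical conformation when related by the
molecule's symmetry: reversing the chain (reading the dihedrals backwards)
and/or taking the mirror image (negating every gauche state).  Unique
conformations are therefore orbits of a small group acting on the 3^n
state vectors; they are produced both by explicit orbit enumeration and by
the orbit-counting (Burnside) lemma as an independent cross-check.

The flagship example is ethylene glycol, HO-CH2-CH2-OH: three consecutive
dihedrals (H-O-C-C, O-C-C-O, C-C-O-H) under the full four-element group
give exactly 10 unique conformations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from . import data
from .chem import Molecule, MoleculeError, ring_info

__all__ = [
    "STATE_ANGLES",
    "TorsionSpec",
    "enumerate_unique_states",
    "count_unique_states_burnside",
    "build_chain_conformer",
    "measure_dihedral",
    "backbone_is_palindromic",
]

#: rotamer alphabet: label -> dihedral angle (degrees)
STATE_ANGLES = {"t": 180.0, "g+": 60.0, "g-": -60.0}

_NEGATE = {"t": "t", "g+": "g-", "g-": "g+"}

VALID_OPS = ("identity", "reversal", "mirror", "reversal_mirror")


def _apply_op(op: str, v: tuple[str, ...]) -> tuple[str, ...]:
    if op == "identity":
        return v
    if op == "reversal":
        return v[::-1]
    if op == "mirror":
        return tuple(_NEGATE[s] for s in v)
    if op == "reversal_mirror":
        return tuple(_NEGATE[s] for s in v[::-1])
    raise ValueError(f"unknown symmetry op {op!r}")


_COMPOSE = {
    ("identity", "identity"): "identity",
    ("identity", "reversal"): "reversal",
    ("identity", "mirror"): "mirror",
    ("identity", "reversal_mirror"): "reversal_mirror",
    ("reversal", "reversal"): "identity",
    ("reversal", "mirror"): "reversal_mirror",
    ("reversal", "reversal_mirror"): "mirror",
    ("mirror", "mirror"): "identity",
    ("mirror", "reversal_mirror"): "reversal",
    ("reversal_mirror", "reversal_mirror"): "identity",
}


def _compose(a: str, b: str) -> str:
    return _COMPOSE.get((a, b)) or _COMPOSE[(b, a)]


@dataclass(frozen=True)
class TorsionSpec:
    """Number of consecutive dihedrals plus the symmetry group acting on
    their state vectors."""

    n_dihedrals: int
    ops: tuple[str, ...] = ("identity",)

    def __post_init__(self) -> None:
        if self.n_dihedrals < 1:
            raise ValueError("need at least one dihedral")
        ops = tuple(dict.fromkeys(self.ops))  # dedupe, keep order
        if "identity" not in ops:
            ops = ("identity",) + ops
        for op in ops:
            if op not in VALID_OPS:
                raise ValueError(f"unknown symmetry op {op!r}")
        for a, b in itertools.product(ops, repeat=2):
            if _compose(a, b) not in ops:
                raise ValueError(
                    f"ops {ops} not closed under composition "
                    f"({a} * {b} = {_compose(a, b)})"
                )
        object.__setattr__(self, "ops", ops)

    @classmethod
    def full(cls, n_dihedrals: int) -> "TorsionSpec":
        return cls(n_dihedrals, VALID_OPS)


def enumerate_unique_states(spec: TorsionSpec) -> list[tuple[str, ...]]:
    """One lexicographically minimal representative per symmetry orbit."""
    reps: set[tuple[str, ...]] = set()
    for v in itertools.product(sorted(STATE_ANGLES), repeat=spec.n_dihedrals):
        reps.add(min(_apply_op(op, v) for op in spec.ops))
    return sorted(reps)


def count_unique_states_burnside(spec: TorsionSpec) -> int:
    """Orbit count via the orbit-counting lemma.

    |orbits| = (1/|G|) * sum over ops of the number of fixed state vectors,
    with per-op fixed-point counts in closed form: the identity fixes all
    3^n vectors; the mirror only the all-trans vector; the reversal any
    vector determined by its first ceil(n/2) entries; their composition any
    vector whose second half is the negated reverse of the first (middle
    entry, if any, forced to trans).
    """
    n = spec.n_dihedrals
    fixed = {
        "identity": 3 ** n,
        "mirror": 1,
        "reversal": 3 ** math.ceil(n / 2),
        "reversal_mirror": 3 ** (n // 2),
    }
    total = sum(fixed[op] for op in spec.ops)
    count, rem = divmod(total, len(spec.ops))
    assert rem == 0, "fixed-point total not divisible by group order"
    return count


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def measure_dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m = np.cross(n1, b1 / np.linalg.norm(b1))
    return math.degrees(math.atan2(np.dot(m, n2), np.dot(n1, n2)))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _nerf(a, b, c, r: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    """Place atom d with |cd| = r, angle(b,c,d) = theta, dihedral(a,b,c,d) = phi."""
    theta, phi = math.radians(theta_deg), math.radians(phi_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array([
        -r * math.cos(theta),
        r * math.sin(theta) * math.cos(phi),
        -r * math.sin(theta) * math.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def backbone_is_palindromic(molecule: Molecule, backbone: list[int]) -> bool:
    """True when the backbone reads the same by element forwards and back,
    making the reversal symmetry op physically meaningful."""
    elems = [molecule.atoms[i].element for i in backbone]
    return elems == elems[::-1]


def build_chain_conformer(molecule: Molecule, backbone: list[int],
                          state_vector: tuple[str, ...] | list[str],
                          bend_angle: float = data.TETRAHEDRAL_ANGLE
                          ) -> np.ndarray:
    """Construct 3-D coordinates realizing the requested rotamer states.

    The backbone must be a simple bonded path covering every non-terminal
    atom; off-backbone substituents must be terminal (hydrogens, halogens)
    and are placed at ideal tetrahedral positions.  Bond lengths come from
    the standard geometry table; every bend angle defaults to tetrahedral.
    Consecutive backbone dihedral k (atoms k..k+3) is set to the angle of
    ``state_vector[k]``.
    """
    n_back = len(backbone)
    if n_back < 4:
        raise MoleculeError("backbone must contain at least 4 atoms")
    if len(set(backbone)) != n_back:
        raise MoleculeError("backbone revisits an atom (not a simple path)")
    if len(state_vector) != n_back - 3:
        raise MoleculeError(
            f"state vector length {len(state_vector)} != "
            f"{n_back - 3} backbone dihedrals"
        )
    for s in state_vector:
        if s not in STATE_ANGLES:
            raise MoleculeError(f"unknown rotamer state {s!r}")
    for a, b in zip(backbone, backbone[1:]):
        if molecule.bond_order(a, b) is None:
            raise MoleculeError(f"backbone atoms {a} and {b} are not bonded")
    ri = ring_info(molecule)
    for a in backbone:
        if ri.smallest_ring_size[a]:
            raise MoleculeError(f"backbone atom {a} lies in a ring")

    elems = molecule.elements()
    adj = molecule.neighbors()
    back_set = set(backbone)
    for i in backbone:
        for j in adj[i]:
            if j not in back_set and len(adj[j]) != 1:
                raise MoleculeError(
                    f"non-terminal substituent atom {j}: the backbone must "
                    "cover every non-terminal atom"
                )

    def blen(i: int, j: int) -> float:
        return data.ideal_bond_length(elems[i], elems[j])

    coords = np.zeros((molecule.n_atoms, 3))
    placed: dict[int, np.ndarray] = {}
    # backbone via sequential placement
    placed[backbone[0]] = np.zeros(3)
    placed[backbone[1]] = np.array([blen(backbone[0], backbone[1]), 0.0, 0.0])
    theta = bend_angle
    r12 = blen(backbone[1], backbone[2])
    placed[backbone[2]] = placed[backbone[1]] + np.array([
        -r12 * math.cos(math.radians(theta)),
        r12 * math.sin(math.radians(theta)), 0.0,
    ])
    for k in range(3, n_back):
        a, b, c, d = (backbone[k - 3], backbone[k - 2],
                      backbone[k - 1], backbone[k])
        phi = STATE_ANGLES[state_vector[k - 3]]
        placed[d] = _nerf(placed[a], placed[b], placed[c],
                          blen(c, d), theta, phi)

    # terminal substituents at ideal positions
    half = math.radians(bend_angle / 2.0)
    for pos, i in enumerate(backbone):
        subs = [j for j in adj[i] if j not in back_set]
        if not subs:
            continue
        known = [placed[j] for j in adj[i] if j in back_set]
        center = placed[i]
        if len(known) >= 2:
            u, v = _unit(known[0] - center), _unit(known[1] - center)
            e1 = _unit(-(u + v))
            e2 = _unit(np.cross(u, v))
            signs = [1.0, -1.0]
            if len(subs) > 2:
                raise MoleculeError(
                    f"atom {i}: more than two substituents with two "
                    "backbone neighbours"
                )
            for j, sign in zip(subs, signs):
                direction = math.cos(half) * e1 + sign * math.sin(half) * e2
                placed[j] = center + blen(i, j) * direction
        else:
            # chain end: distribute substituents on the tetrahedral cone
            # around the single backbone bond
            u = _unit(known[0] - center)
            ref = np.array([0.0, 0.0, 1.0])
            if abs(np.dot(ref, u)) > 0.99:
                ref = np.array([0.0, 1.0, 0.0])
            e2 = _unit(np.cross(u, ref))
            e3 = np.cross(u, e2)
            t = math.radians(bend_angle)
            for m_idx, j in enumerate(subs):
                az = 2.0 * math.pi * m_idx / max(len(subs), 1)
                direction = (math.cos(t) * u
                             + math.sin(t) * (math.cos(az) * e2
                                              + math.sin(az) * e3))
                placed[j] = center + blen(i, j) * direction

    missing = [i for i in range(molecule.n_atoms) if i not in placed]
    if missing:
        raise MoleculeError(f"atoms {missing} not reachable from backbone")
    for i, xyz in placed.items():
        coords[i] = xyz
    return coords
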