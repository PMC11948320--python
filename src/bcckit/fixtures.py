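"""Seeded synthetic molecules, correction tables and conformer ensembles.

Everything the test and demo workflows need is generated here from one
integer seed: valence-correct random molecular graphs with a 3-D
embedding, random bond-charge-correction tables over their key sets, and
conformer ensembles produced by Gaussian geometry jitter (bond lengths
re-idealized) followed by electronegativity-equalization charges — a
deliberately conformation-sensitive base-charge ensemble for fluctuation
analysis.  These ensembles emulate the *mechanics* of conformational
charge variation, not Boltzmann-weighted physical ensembles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import data
from .atom_typing import assign_atom_types, assign_bond_keys
from .charges import BCCTable, EEMParams, PreChargeSet, precharges_eem
from .chem import Atom, Bond, Molecule, check_valences

__all__ = [
    "FixtureSpec",
    "synth_molecule",
    "synth_bcc_table",
    "synth_conformer_charges",
    "jitter_conformer",
]

_VALENCE = {"H": 1, "C": 4, "N": 3, "O": 2, "S": 2, "P": 3,
            "F": 1, "Cl": 1, "Br": 1, "I": 1}


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic generator; the seed fixes everything."""

    seed: int = 0
    n_heavy: tuple[int, int] = (4, 9)
    elements: dict = field(default_factory=lambda: {"C": 6.0, "O": 2.0,
                                                    "N": 1.0})
    ring_probability: float = 0.0
    conformer_count: int = 1
    jitter: float = 0.05  # Gaussian displacement scale, Angstrom
    bcc_scale: float = 0.1  # correction magnitude bound, e

    def __post_init__(self) -> None:
        lo, hi = self.n_heavy
        if not 1 <= lo <= hi:
            raise FixtureError("invalid heavy-atom range")
        if self.jitter < 0 or self.bcc_scale < 0:
            raise FixtureError("jitter and bcc_scale must be >= 0")
        if not 0 <= self.ring_probability <= 1:
            raise FixtureError("ring_probability must be in [0, 1]")
        if any(el not in _VALENCE or el == "H" for el in self.elements):
            raise FixtureError("palette must be heavy atoms from the "
                               "supported element set")


def _pick(rng: np.random.Generator, palette: dict) -> str:
    items = sorted(palette)
    weights = np.array([palette[e] for e in items], float)
    return items[rng.choice(len(items), p=weights / weights.sum())]


def synth_molecule(spec: FixtureSpec,
                   rng: np.random.Generator | None = None) -> Molecule:
    """Grow a random valence-correct molecule and embed it in 3-D.

    The heavy-atom skeleton is grown as a tree (optionally seeded from a
    ring template with probability ``ring_probability``); remaining
    valences are filled with hydrogens; coordinates come from an
    internal-coordinate breadth-first embedding with ideal bond lengths.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    growable = [e for e in spec.elements if _VALENCE[e] >= 2]
    lo, hi = spec.n_heavy
    n_heavy = int(rng.integers(lo, hi + 1))
    if n_heavy > 1 and not growable:
        raise FixtureError(
            "palette has no element of valence >= 2; cannot grow a skeleton"
        )

    elements: list[str] = []
    bonds: list[tuple[int, int]] = []
    use_ring = (spec.ring_probability > 0
                and rng.random() < spec.ring_probability
                and n_heavy >= 6 and "C" in growable)
    if use_ring:
        ring_size = int(rng.choice([5, 6]))
        elements = ["C"] * ring_size
        bonds = [(i, (i + 1) % ring_size) for i in range(ring_size)]
    else:
        elements = [_pick(rng, spec.elements)]
        if n_heavy > 1 and _VALENCE[elements[0]] < 2:
            elements[0] = growable[int(rng.integers(len(growable)))]

    def free_valence(i: int) -> int:
        used = sum(1 for a, b in bonds if i in (a, b))
        return _VALENCE[elements[i]] - used

    while len(elements) < n_heavy:
        open_atoms = [i for i in range(len(elements)) if free_valence(i) > 0]
        if not open_atoms:
            break  # skeleton saturated early (e.g. all-O chain)
        anchor = open_atoms[int(rng.integers(len(open_atoms)))]
        remaining = n_heavy - len(elements)
        el = _pick(rng, spec.elements)
        if remaining > 1 and _VALENCE[el] < 2 and all(
            free_valence(i) == 0 for i in range(len(elements)) if i != anchor
        ) and free_valence(anchor) == 1:
            el = growable[int(rng.integers(len(growable)))]
        elements.append(el)
        bonds.append((anchor, len(elements) - 1))

    # hydrogen completion
    n_skel = len(elements)
    for i in range(n_skel):
        for _ in range(free_valence(i)):
            elements.append("H")
            bonds.append((i, len(elements) - 1))

    atoms = [Atom(k, el) for k, el in enumerate(elements)]
    bond_objs = [Bond(a, b, "single") for a, b in bonds]
    coords = _embed(elements, bonds, n_ring=(ring_size if use_ring else 0),
                    rng=rng)
    mol = Molecule(f"synth-{spec.seed}", atoms, bond_objs, [coords])
    check_valences(mol)
    return mol


def _embed(elements: list[str], bonds: list[tuple[int, int]],
           n_ring: int, rng: np.random.Generator) -> np.ndarray:
    """Breadth-first internal-coordinate embedding.

    Ring template atoms sit on a regular polygon; every other atom is
    placed on a tetrahedral cone around its parent bond with a randomized
    azimuth, which keeps the geometry non-degenerate for the EEM solve.
    """
    n = len(elements)
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    coords = np.zeros((n, 3))
    placed = [False] * n
    theta = math.radians(data.TETRAHEDRAL_ANGLE)

    if n_ring:
        r_bond = data.ideal_bond_length("C", "C")
        radius = r_bond / (2.0 * math.sin(math.pi / n_ring))
        for i in range(n_ring):
            ang = 2.0 * math.pi * i / n_ring
            coords[i] = [radius * math.cos(ang), radius * math.sin(ang), 0.0]
            placed[i] = True
        queue = list(range(n_ring))
        parent = {i: ((i - 1) % n_ring) for i in range(n_ring)}
    else:
        placed[0] = True
        queue = [0]
        parent = {0: None}

    while queue:
        i = queue.pop(0)
        children = [j for j in adj[i] if not placed[j]]
        if not children:
            continue
        if parent.get(i) is None:
            axes = np.array([[1.0, 0, 0], [-1 / 3, 2 * 2 ** 0.5 / 3, 0],
                             [-1 / 3, -(2 ** 0.5) / 3, (6 ** 0.5) / 3],
                             [-1 / 3, -(2 ** 0.5) / 3, -(6 ** 0.5) / 3]])
            for k, j in enumerate(children):
                r = data.ideal_bond_length(elements[i], elements[j])
                coords[j] = coords[i] + r * axes[k % 4]
                placed[j] = True
                parent[j] = i
                queue.append(j)
            continue
        known = [coords[p] for p in adj[i] if placed[p]]
        u = _unit_mean(np.array(known) - coords[i])
        ref = np.array([0.0, 0.0, 1.0])
        if abs(float(np.dot(ref, u))) > 0.99:
            ref = np.array([0.0, 1.0, 0.0])
        e2 = np.cross(u, ref)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(u, e2)
        az0 = rng.uniform(0.0, 2.0 * math.pi)
        for k, j in enumerate(children):
            az = az0 + 2.0 * math.pi * k / max(len(children), 1)
            d = (math.cos(theta) * u
                 + math.sin(theta) * (math.cos(az) * e2 + math.sin(az) * e3))
            r = data.ideal_bond_length(elements[i], elements[j])
            coords[j] = coords[i] + r * d
            placed[j] = True
            parent[j] = i
            queue.append(j)
    # nudge any accidental near-contacts apart deterministically
    for _ in range(50):
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        ii, jj = np.unravel_index(np.argmin(d), d.shape)
        if d[ii, jj] > 0.7:
            break
        direction = coords[ii] - coords[jj]
        norm = np.linalg.norm(direction)
        direction = (direction / norm if norm > 1e-9
                     else rng.standard_normal(3))
        coords[ii] += 0.25 * direction
    return coords


def _unit_mean(vectors: np.ndarray) -> np.ndarray:
    m = vectors.mean(axis=0)
    n = np.linalg.norm(m)
    if n < 1e-9:
        m = vectors[0]
        n = np.linalg.norm(m)
    return m / n


def synth_bcc_table(spec: FixtureSpec,
                    keys: list[tuple[str, str, str]],
                    rng: np.random.Generator | None = None) -> BCCTable:
    """Random correction table over the given canonical keys, values
    uniform in +-bcc_scale; self-pair keys are skipped."""
    if not keys:
        raise FixtureError("no keys supplied")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    values = {}
    for pair in sorted(set(keys)):
        if pair[0] == pair[1]:
            continue
        values[pair] = float(rng.uniform(-spec.bcc_scale, spec.bcc_scale))
    return BCCTable(values=values, name=f"synth-{spec.seed}")


def jitter_conformer(molecule: Molecule, magnitude: float,
                     rng: np.random.Generator,
                     conformer: int = 0) -> np.ndarray:
    """Gaussian-displaced copy of a conformer with bond lengths restored.

    After displacement, 30 rounds of pairwise projection pull each bonded
    pair back to its original length (a SHAKE-style relaxation), so the
    jitter perturbs angles and torsions but keeps bonds near-ideal.
    """
    base = molecule.conformers[conformer]
    coords = base + rng.normal(0.0, magnitude, size=base.shape)
    targets = [
        (b.i, b.j, float(np.linalg.norm(base[b.i] - base[b.j])))
        for b in molecule.bonds
    ]
    for _ in range(30 if magnitude > 0 else 0):
        for i, j, l0 in targets:
            d = coords[i] - coords[j]
            length = np.linalg.norm(d)
            if length < 1e-9:
                continue
            corr = 0.5 * (length - l0) / length * d
            coords[i] -= corr
            coords[j] += corr
    return coords


def synth_conformer_charges(molecule: Molecule, spec: FixtureSpec,
                            params: EEMParams | None = None,
                            rng: np.random.Generator | None = None
                            ) -> tuple[list[np.ndarray], list[PreChargeSet]]:
    """Jittered conformer ensemble with EEM base charges per conformer.

    Returns the conformer coordinate list and the matching pre-charge
    sets; the expected charge fluctuation grows with the jitter
    magnitude.  With zero jitter all sets are identical.
    """
    if spec.conformer_count < 2:
        raise FixtureError("need at least two conformers")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    params = params or EEMParams.default()
    work = Molecule(molecule.name, molecule.atoms, molecule.bonds,
                    [molecule.conformers[0]])
    conf_coords: list[np.ndarray] = []
    charge_sets: list[PreChargeSet] = []
    for c in range(spec.conformer_count):
        coords = jitter_conformer(molecule, spec.jitter, rng)
        work.conformers = [coords]
        pcs = precharges_eem(work, 0, params)
        conf_coords.append(coords)
        charge_sets.append(PreChargeSet(pcs.charges, "eem", conformer_id=c))
    return conf_coords, charge_sets


def molecule_keys(molecule: Molecule) -> list[tuple[str, str, str]]:
    """Canonical key pairs present in a molecule (helper for table synth)."""
    types = assign_atom_types(molecule)
    return [k.pair for k in assign_bond_keys(molecule, types)]
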