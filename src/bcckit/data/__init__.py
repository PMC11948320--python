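"""Bundled constant tables (covalent radii, EEM parameters, typing rules)."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources


def _lines(name: str) -> list[str]:
    text = (resources.files(__package__) / name).read_text()
    return [
        ln for ln in (raw.strip() for raw in text.splitlines())
        if ln and not ln.startswith("#")
    ]


@lru_cache(maxsize=None)
def covalent_radii() -> dict[str, float]:
    """Covalent radius per element, Angstrom."""
    out = {}
    for ln in _lines("covalent_radii.tsv"):
        el, r = ln.split()
        out[el] = float(r)
    return out


@lru_cache(maxsize=None)
def eem_parameters() -> dict[str, tuple[float, float]]:
    """(chi [V], eta [V/e]) per element for the stand-in EEM model."""
    out = {}
    for ln in _lines("eem_params.tsv"):
        el, chi, eta = ln.split()
        out[el] = (float(chi), float(eta))
    return out


@lru_cache(maxsize=None)
def bond_lengths() -> dict[tuple[str, str], float]:
    """Ideal bond length per unordered element pair, Angstrom."""
    out = {}
    for ln in _lines("geometry.tsv"):
        a, b, length = ln.split()
        out[(a, b)] = out[(b, a)] = float(length)
    return out


def ideal_bond_length(elem_a: str, elem_b: str) -> float:
    """Ideal length for a bond, falling back to summed covalent radii."""
    table = bond_lengths()
    if (elem_a, elem_b) in table:
        return table[(elem_a, elem_b)]
    radii = covalent_radii()
    return radii[elem_a] + radii[elem_b]


def default_rules_text() -> str:
    return (resources.files(__package__) / "atom_type_rules.tsv").read_text()


def default_bcc_text() -> str:
    return (resources.files(__package__) / "default_bcc.tsv").read_text()


#: Tolerance added to summed covalent radii for xyz bond perception (A).
PERCEPTION_TOLERANCE = 0.4

#: Coulomb constant for the EEM model, V*Angstrom/e.
EEM_KAPPA = 14.4

#: Tetrahedral angle, degrees.
TETRAHEDRAL_ANGLE = 109.47122063449069
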