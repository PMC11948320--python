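"""Charge generation and bond-charge-correction application.

The central computation is ``q = p + A b``: per-atom base charges ``p``
(read from file or produced by the electronegativity-equalization stand-in),
corrected by a table ``b`` of per-bond-type charge transfers through the
oriented bond/key incidence matrix ``A``.  Because every bond moves charge
between exactly two atoms, total charge is conserved identically — the
structural reason corrected charges depend on conformation only through
the base charges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, TextIO

import numpy as np

from . import data
from .atom_typing import BOND_CLASSES, BondTypeKey
from .chem import EquivalencePartition, Molecule

__all__ = [
    "EEMParams",
    "PreChargeSet",
    "ChargeSet",
    "BCCTable",
    "precharges_eem",
    "normalize_precharges",
    "apply_bcc",
    "incidence_matrix",
    "symmetrize_charges",
]

log = logging.getLogger(__name__)

#: residual above which a file precharge set is treated as an error
#: rather than silently renormalized (e)
PRECHARGE_RESIDUAL_TOLERANCE = 1e-3


class ChargeError(ValueError):
    pass


@dataclass(frozen=True)
class EEMParams:
    """Electronegativity chi (V) and hardness eta (V/e) per element.

    ``kappa`` scales the pairwise Coulomb coupling kappa / r_ij; the
    default 14.4 V*A/e is the vacuum Coulomb constant in eV units.
    """

    chi: Mapping[str, float]
    eta: Mapping[str, float]
    kappa: float = data.EEM_KAPPA

    def __post_init__(self) -> None:
        for el, eta in self.eta.items():
            if eta <= 0:
                raise ChargeError(f"hardness for {el} must be positive")

    @classmethod
    def default(cls) -> "EEMParams":
        table = data.eem_parameters()
        return cls(chi={el: v[0] for el, v in table.items()},
                   eta={el: v[1] for el, v in table.items()})


@dataclass(frozen=True)
class PreChargeSet:
    """Base (pre-BCC) per-atom charges for one conformer."""

    charges: np.ndarray
    provenance: str = "file"  # file | eem | zero-spread
    conformer_id: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "charges",
                           np.asarray(self.charges, dtype=float))


@dataclass(frozen=True)
class ChargeSet:
    """Final per-atom charges; sums exactly to the molecule's net charge."""

    charges: np.ndarray
    provenance: str
    conformer_id: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "charges",
                           np.asarray(self.charges, dtype=float))


@dataclass
class BCCTable:
    """Bond-charge corrections, keyed by canonical (type_a, type_b, class).

    Self-pair keys (type_a == type_b) are rejected: the antisymmetric
    construction forces their correction to zero, so a nonzero entry would
    be inconsistent and a zero entry redundant.
    """

    values: dict[tuple[str, str, str], float] = field(default_factory=dict)
    name: str = "bcc"
    version: str = "0"

    def __post_init__(self) -> None:
        for (a, b, cls), v in self.values.items():
            if cls not in BOND_CLASSES:
                raise ChargeError(f"unknown bond class {cls!r}")
            if a == b:
                raise ChargeError(f"self-pair key {a}-{b} not permitted")
            if a > b:
                raise ChargeError(f"non-canonical key ({a},{b})")
            if not np.isfinite(v):
                raise ChargeError(f"non-finite value for key ({a},{b},{cls})")

    def lookup(self, key: BondTypeKey) -> float | None:
        """Correction at the ``Bond.i`` end of a bond carrying ``key``.

        Returns the table value times the key's orientation (the value is
        defined along the canonical direction), or None when absent.
        Same-type keys are structurally zero.
        """
        if key.is_self_pair:
            return 0.0
        v = self.values.get(key.pair)
        return None if v is None else key.orientation * v

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_text(cls, source: str | Path | TextIO,
                  name: str = "bcc") -> "BCCTable":
        from .io import as_text

        text = as_text(source)
        values: dict[tuple[str, str, str], float] = {}
        for ln_no, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ChargeError(f"line {ln_no}: expected 4 fields")
            a, b, cls_, v = parts
            value = float(v)
            if a == b:
                raise ChargeError(
                    f"line {ln_no}: self-pair entry {a}-{b} not permitted"
                )
            if a > b:
                a, b, value = b, a, -value  # canonicalize, flipping the sign
            key = (a, b, cls_)
            if key in values:
                raise ChargeError(f"line {ln_no}: duplicate key {key}")
            values[key] = value
        return cls(values=values, name=name)

    def to_text(self) -> str:
        lines = [f"# BCC table: {self.name} (version {self.version})",
                 "# type_a\ttype_b\tbond_class\tvalue_e"]
        for (a, b, cls_), v in sorted(self.values.items()):
            lines.append(f"{a}\t{b}\t{cls_}\t{v:.6f}")
        return "\n".join(lines) + "\n"

    @classmethod
    def default(cls) -> "BCCTable":
        return cls.from_text(data.default_bcc_text(), name="bcckit-default")


# ---------------------------------------------------------------------------
# EEM pre-charges
# ---------------------------------------------------------------------------

def precharges_eem(molecule: Molecule, conformer: int = 0,
                   params: EEMParams | None = None,
                   net_charge: int | None = None) -> PreChargeSet:
    """Electronegativity-equalization charges for one conformer.

    Solves the stationarity system of E(q) = sum_i (chi_i q_i + eta_i q_i^2)
    + sum_{i<j} kappa q_i q_j / r_ij under the total-charge constraint:
    an (n+1)-dimensional symmetric linear system with a Lagrange
    multiplier.  Geometry-dependent by construction, which is what makes
    it a useful conformation-sensitive base-charge provider.
    """
    params = params or EEMParams.default()
    if net_charge is None:
        net_charge = molecule.net_charge
    if not molecule.conformers:
        raise ChargeError("molecule has no conformer coordinates")
    coords = molecule.conformers[conformer]
    n = molecule.n_atoms
    for el in set(molecule.elements()):
        if el not in params.chi or el not in params.eta:
            raise ChargeError(f"no EEM parameters for element {el}")
    if n == 1:
        return PreChargeSet(np.array([float(net_charge)]), "eem", conformer)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    if np.any(dist[~np.eye(n, dtype=bool)] < 1e-6):
        raise ChargeError("coincident atoms: EEM system singular")
    m = np.zeros((n + 1, n + 1))
    with np.errstate(divide="ignore"):
        coupling = np.where(np.eye(n, dtype=bool), 0.0, params.kappa / dist)
    m[:n, :n] = coupling
    m[np.arange(n), np.arange(n)] = [
        2.0 * params.eta[el] for el in molecule.elements()
    ]
    m[:n, n] = 1.0
    m[n, :n] = 1.0
    rhs = np.zeros(n + 1)
    rhs[:n] = [-params.chi[el] for el in molecule.elements()]
    rhs[n] = float(net_charge)
    try:
        sol = np.linalg.solve(m, rhs)
    except np.linalg.LinAlgError as exc:
        raise ChargeError(f"EEM system singular: {exc}") from None
    q = sol[:n]
    q = q + (net_charge - q.sum()) / n  # remove O(machine-eps) drift
    return PreChargeSet(q, "eem", conformer)


def normalize_precharges(charges: np.ndarray, net_charge: int,
                         tolerance: float = PRECHARGE_RESIDUAL_TOLERANCE
                         ) -> PreChargeSet:
    """Spread a small residual uniformly so the sum is exact.

    Rounded file columns rarely sum exactly to the net charge; a residual
    above ``tolerance`` (default 1e-3 e) indicates a wrong net charge and
    raises instead.
    """
    charges = np.asarray(charges, dtype=float)
    residual = float(net_charge) - charges.sum()
    if abs(residual) > tolerance:
        raise ChargeError(
            f"precharge sum {charges.sum():.6f} differs from net charge "
            f"{net_charge} by {residual:+.6f} e (tolerance {tolerance} e)"
        )
    provenance = "file" if residual == 0 else "zero-spread"
    return PreChargeSet(charges + residual / len(charges), provenance)


# ---------------------------------------------------------------------------
# BCC application
# ---------------------------------------------------------------------------

def apply_bcc(molecule: Molecule, atom_types: Sequence[str],
              bond_keys: Sequence[BondTypeKey], precharges: PreChargeSet,
              table: BCCTable, strict: bool = False) -> ChargeSet:
    """Apply bond-charge corrections: q_i = p_i + sum over bonds of ±b.

    For each bond carrying canonical key (alpha, beta) with value b, b is
    added at the alpha end and subtracted at the beta end.  A key absent
    from the table aborts in strict mode; otherwise it contributes zero
    and is logged.
    """
    if len(bond_keys) != len(molecule.bonds):
        raise ChargeError("bond_keys length mismatch")
    q = precharges.charges.astype(float).copy()
    if q.shape != (molecule.n_atoms,):
        raise ChargeError("precharge length mismatch")
    for bond, key in zip(molecule.bonds, bond_keys):
        delta = table.lookup(key)
        if delta is None:
            if strict:
                raise ChargeError(
                    f"no BCC value for key {key.pair} "
                    f"(bond {bond.i}-{bond.j})"
                )
            log.warning("no BCC value for key %s (bond %d-%d); using 0",
                        key.pair, bond.i, bond.j)
            continue
        q[bond.i] += delta
        q[bond.j] -= delta
    return ChargeSet(q, provenance=f"{precharges.provenance}+{table.name}",
                     conformer_id=precharges.conformer_id)


def incidence_matrix(molecule: Molecule, bond_keys: Sequence[BondTypeKey],
                     key_order: Sequence[tuple[str, str, str]]) -> np.ndarray:
    """Oriented atom x key incidence matrix A with apply_bcc = p + A b.

    Entry A[i, k] counts bonds at atom i traversed along the canonical
    direction of key k, minus those traversed against it.  Every column
    sums to zero.  Self-pair keys are structurally zero and may not appear
    in ``key_order``; bonds with keys outside ``key_order`` contribute
    nothing (the warn-and-zero path).
    """
    col = {}
    for k, pair in enumerate(key_order):
        if pair[0] == pair[1]:
            raise ChargeError(f"self-pair key {pair} has no column")
        col[pair] = k
    a = np.zeros((molecule.n_atoms, len(key_order)))
    for bond, key in zip(molecule.bonds, bond_keys):
        k = col.get(key.pair)
        if k is None:
            continue
        a[bond.i, k] += key.orientation
        a[bond.j, k] -= key.orientation
    return a


def symmetrize_charges(chargeset: ChargeSet,
                       partition: EquivalencePartition) -> ChargeSet:
    """Average charges within each topological-equivalence class.

    Idempotent and exactly charge-conserving (class means redistribute
    charge only within classes).  Off by default in assignment workflows:
    conformational symmetry breaking is precisely what the fluctuation
    analysis measures.
    """
    q = chargeset.charges
    if len(partition.class_ids) != len(q):
        raise ChargeError("partition does not match charge vector")
    out = q.astype(float).copy()
    for members in partition.members().values():
        out[members] = q[members].mean()
    return ChargeSet(out, chargeset.provenance + "+sym",
                     chargeset.conformer_id)
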