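"""Linear least-squares estimation of bond-charge-correction parameters.

Targets are per-atom reference charges or electrostatic-potential (ESP)
samples; both reduce to the linear model t = p + D b, where D stacks the
oriented bond/key incidence matrices (for ESP targets, premultiplied by the
Coulomb kernel).  Free-energy targets are deliberately not accepted: tuning
corrections against experimental solvation data needs a full simulation
loop and sits outside a desk-scale fit.

BCC designs are routinely rank-deficient — two bond types that only ever
appear in a fixed ratio cannot be separated — so the fit returns the
minimum-norm solution and reports a basis of the unidentifiable key
combinations rather than failing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atom_typing import AtomTypeRule, assign_atom_types, assign_bond_keys
from .charges import BCCTable, ChargeSet, PreChargeSet, apply_bcc, incidence_matrix
from .chem import Molecule

__all__ = [
    "COULOMB_KCAL",
    "TrainingRecord",
    "FitResult",
    "build_design",
    "fit_bcc",
    "predict_charges",
]

#: Coulomb constant in kcal*Angstrom/(mol*e^2); ESP values are expected in
#: kcal/(mol*e).
COULOMB_KCAL = 332.0637


class FitError(ValueError):
    pass


@dataclass(frozen=True)
class TrainingRecord:
    """One molecule with base charges and a reference target.

    Exactly one of ``target_charges`` (per-atom, e) or the ESP pair
    ``esp_points`` ((m, 3) grid, Angstrom) + ``esp_values`` (kcal/(mol*e))
    must be provided.
    """

    molecule: Molecule
    precharges: PreChargeSet
    target_charges: np.ndarray | None = None
    esp_points: np.ndarray | None = None
    esp_values: np.ndarray | None = None
    conformer: int = 0

    def __post_init__(self) -> None:
        has_q = self.target_charges is not None
        has_esp = self.esp_points is not None and self.esp_values is not None
        if has_q == has_esp:
            raise FitError(
                "provide either target_charges or esp_points/esp_values"
            )
        if has_q and len(self.target_charges) != self.molecule.n_atoms:
            raise FitError("target charge length mismatch")
        if has_esp and len(self.esp_points) != len(self.esp_values):
            raise FitError("ESP grid/value length mismatch")


@dataclass
class FitResult:
    """Fitted correction vector plus identifiability diagnostics."""

    key_order: list[tuple[str, str, str]]
    b: np.ndarray
    per_molecule_residual: list[float]
    nullspace: np.ndarray  # (n_keys, nullity) orthonormal basis
    ridge: float
    rank: int

    @property
    def nullspace_dim(self) -> int:
        return self.nullspace.shape[1]

    def as_table(self, name: str = "fitted") -> BCCTable:
        values = {pair: float(v)
                  for pair, v in zip(self.key_order, self.b)}
        return BCCTable(values=values, name=name)


def _esp_kernel(points: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """(m, n) matrix k / |r_m - r_i| mapping charges to potentials."""
    d = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=-1)
    if np.any(d < 1e-6):
        raise FitError("ESP grid point coincides with an atom")
    return COULOMB_KCAL / d


def build_design(training: list[TrainingRecord],
                 rules: list[AtomTypeRule] | None = None):
    """Stack per-record designs over the union key order.

    Returns ``(design, baseline, target, key_order, row_slices)`` with the
    model ``target = baseline + design @ b``.  Charge-target records
    contribute one row per atom (the incidence matrix); ESP records one row
    per grid point (Coulomb kernel times incidence matrix).
    """
    if not training:
        raise FitError("empty training set")
    typed = []
    pair_set: set[tuple[str, str, str]] = set()
    for rec in training:
        types = assign_atom_types(rec.molecule, rules)
        keys = assign_bond_keys(rec.molecule, types)
        typed.append(keys)
        pair_set.update(k.pair for k in keys if not k.is_self_pair)
    key_order = sorted(pair_set)
    blocks, baselines, targets, slices = [], [], [], []
    row = 0
    for rec, keys in zip(training, typed):
        a = incidence_matrix(rec.molecule, keys, key_order)
        p = rec.precharges.charges
        if rec.target_charges is not None:
            d, base, t = a, p, np.asarray(rec.target_charges, float)
        else:
            coords = rec.molecule.conformers[rec.conformer]
            g = _esp_kernel(np.asarray(rec.esp_points, float), coords)
            d, base, t = g @ a, g @ p, np.asarray(rec.esp_values, float)
        blocks.append(d)
        baselines.append(base)
        targets.append(t)
        slices.append(slice(row, row + len(t)))
        row += len(t)
    return (np.vstack(blocks), np.concatenate(baselines),
            np.concatenate(targets), key_order, slices)


def fit_bcc(training: list[TrainingRecord], ridge: float = 0.0,
            rules: list[AtomTypeRule] | None = None) -> FitResult:
    """Minimize ||t - p - D b||^2 + ridge ||b||^2.

    With ridge = 0 the minimum-norm least-squares solution is returned
    (SVD pseudoinverse); the right singular vectors with negligible
    singular value form the reported null-space basis of unidentifiable
    key combinations.
    """
    if ridge < 0:
        raise FitError("ridge weight must be >= 0")
    design, baseline, target, key_order, slices = build_design(training, rules)
    y = target - baseline
    u, s, vt = np.linalg.svd(design, full_matrices=True)
    tol = max(design.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if ridge == 0.0:
        inv_s = np.zeros_like(s)
        inv_s[:rank] = 1.0 / s[:rank]
        b = vt[: len(s)].T @ (inv_s * (u.T[: len(s)] @ y))
    else:
        filt = s / (s**2 + ridge)
        b = vt[: len(s)].T @ (filt * (u.T[: len(s)] @ y))
    nullspace = vt[rank:].T  # (n_keys, nullity)
    resid = y - design @ b
    per_mol = [float(np.linalg.norm(resid[sl])) for sl in slices]
    return FitResult(key_order=key_order, b=b,
                     per_molecule_residual=per_mol,
                     nullspace=nullspace, ridge=ridge, rank=rank)


def predict_charges(fit: FitResult, molecule: Molecule,
                    precharges: PreChargeSet,
                    rules: list[AtomTypeRule] | None = None,
                    strict: bool = False) -> ChargeSet:
    """Apply the fitted table to a molecule (same contract as apply_bcc)."""
    types = assign_atom_types(molecule, rules)
    keys = assign_bond_keys(molecule, types)
    return apply_bcc(molecule, types, keys, precharges,
                     fit.as_table(), strict=strict)
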