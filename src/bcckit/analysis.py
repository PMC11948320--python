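"""Conformational charge-fluctuation statistics and point-charge multipoles.

A charge model's conformational dependence is measured by assigning charges
to the same molecule in several conformations and taking, per atom, the
standard deviation across conformers ("fluctuation", e).  Reporting is
per atom, per topological-equivalence class (mean over class members), and
molecule-averaged (mean over all atoms) — so per-class values weighted by
class size recover the molecule average exactly.

Point-charge dipoles (Debye) and quadrupoles (Debye*Angstrom) support the
companion electrostatics validation: model multipoles per conformer are
compared against reference values by per-component RMSE and R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import EquivalencePartition, Molecule

__all__ = [
    "DEBYE_PER_E_ANGSTROM",
    "FluctuationReport",
    "MultipoleSet",
    "charge_fluctuations",
    "dipole",
    "quadrupole",
    "compare_multipoles",
]

#: 1 e*Angstrom in Debye
DEBYE_PER_E_ANGSTROM = 4.80320

DIPOLE_COMPONENTS = ("dx", "dy", "dz", "dm")
QUADRUPOLE_COMPONENTS = ("qxx", "qyy", "qzz", "qxy", "qxz", "qyz")


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class FluctuationReport:
    """Charge STDs across conformers at three aggregation levels."""

    per_atom: np.ndarray  # (n_atoms,) STD in e
    per_class: dict[int, float] | None  # class id -> mean member STD
    molecule_average: float  # mean of per-atom STDs
    n_conformers: int
    ddof: int = 0


def charge_fluctuations(charge_sets: list[np.ndarray],
                        partition: EquivalencePartition | None = None,
                        ddof: int = 0) -> FluctuationReport:
    """Per-atom charge STD over >= 2 conformer charge sets.

    ``ddof=0`` (population STD over the given conformations) is the
    default; the choice is recorded in the report.  All sets must follow
    one atom ordering.
    """
    if len(charge_sets) < 2:
        raise AnalysisError("need at least two conformer charge sets")
    vectors = [np.asarray(c, float) for c in charge_sets]
    if len({v.shape for v in vectors}) != 1 or vectors[0].ndim != 1:
        raise AnalysisError("charge sets have inconsistent lengths")
    arr = np.asarray(vectors)
    per_atom = arr.std(axis=0, ddof=ddof)
    per_class = None
    if partition is not None:
        if len(partition.class_ids) != arr.shape[1]:
            raise AnalysisError("partition does not match charge sets")
        per_class = {
            cid: float(per_atom[members].mean())
            for cid, members in partition.members().items()
        }
    return FluctuationReport(
        per_atom=per_atom,
        per_class=per_class,
        molecule_average=float(per_atom.mean()),
        n_conformers=arr.shape[0],
        ddof=ddof,
    )


@dataclass(frozen=True)
class MultipoleSet:
    """Dipole (Debye) and quadrupole (Debye*Angstrom) of one conformer."""

    dx: float
    dy: float
    dz: float
    dm: float
    qxx: float
    qyy: float
    qzz: float
    qxy: float
    qxz: float
    qyz: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    convention: str = "traceless"

    def component(self, name: str) -> float:
        return getattr(self, name)


def dipole(coords: np.ndarray, charges: np.ndarray,
           origin: np.ndarray | None = None
           ) -> tuple[float, float, float, float]:
    """Point-charge dipole (dx, dy, dz, dm) in Debye.

    p = sum_i q_i (r_i - origin); origin-independent when the total charge
    is zero.
    """
    coords = np.asarray(coords, float)
    charges = np.asarray(charges, float)
    if origin is None:
        origin = np.zeros(3)
    rel = coords - np.asarray(origin, float)
    p = DEBYE_PER_E_ANGSTROM * charges @ rel
    return (float(p[0]), float(p[1]), float(p[2]),
            float(np.linalg.norm(p)))


def quadrupole(coords: np.ndarray, charges: np.ndarray,
               convention: str = "traceless",
               origin: np.ndarray | None = None
               ) -> tuple[float, float, float, float, float, float]:
    """Point-charge quadrupole (qxx, qyy, qzz, qxy, qxz, qyz), Debye*Angstrom.

    ``second-moment``: Q_ab = sum_i q_i r_a r_b.
    ``traceless``:     Theta_ab = sum_i q_i (3 r_a r_b - r^2 delta_ab) / 2.
    Default origin is the geometric centroid of the coordinates.
    """
    if convention not in ("traceless", "second-moment"):
        raise AnalysisError(f"unknown quadrupole convention {convention!r}")
    coords = np.asarray(coords, float)
    charges = np.asarray(charges, float)
    if origin is None:
        origin = coords.mean(axis=0)
    rel = coords - np.asarray(origin, float)
    q = np.einsum("i,ia,ib->ab", charges, rel, rel)
    if convention == "traceless":
        q = (3.0 * q - np.trace(q) * np.eye(3)) / 2.0
    q = DEBYE_PER_E_ANGSTROM * q
    return (float(q[0, 0]), float(q[1, 1]), float(q[2, 2]),
            float(q[0, 1]), float(q[0, 2]), float(q[1, 2]))


def multipoles(molecule: Molecule, charges: np.ndarray, conformer: int = 0,
               convention: str = "traceless") -> MultipoleSet:
    """Dipole about the origin and quadrupole about the centroid."""
    coords = molecule.conformers[conformer]
    dx, dy, dz, dm = dipole(coords, charges)
    qxx, qyy, qzz, qxy, qxz, qyz = quadrupole(coords, charges, convention)
    centroid = tuple(float(v) for v in coords.mean(axis=0))
    return MultipoleSet(dx, dy, dz, dm, qxx, qyy, qzz, qxy, qxz, qyz,
                        origin=centroid, convention=convention)


def compare_multipoles(mm: list[MultipoleSet], ref: list[MultipoleSet]
                       ) -> dict[str, dict[str, float]]:
    """Per-component RMSE and R^2 of model vs reference across conformers.

    Returns ``{component: {"rmse": ..., "r2": ...}}`` over the ten
    components plus ``"summary"`` with mean dipole/quadrupole RMSEs.  R^2
    is the squared Pearson correlation and is NaN when either series is
    constant.
    """
    if len(mm) != len(ref) or len(mm) < 2:
        raise AnalysisError("need matched multipole lists with >= 2 conformers")
    for a, b in zip(mm, ref):
        if a.convention != b.convention:
            raise AnalysisError(
                f"convention mismatch: {a.convention} vs {b.convention}"
            )
    out: dict[str, dict[str, float]] = {}
    names = DIPOLE_COMPONENTS + QUADRUPOLE_COMPONENTS
    for name in names:
        x = np.array([m.component(name) for m in mm])
        y = np.array([r.component(name) for r in ref])
        rmse = float(np.sqrt(np.mean((x - y) ** 2)))
        if np.std(x) == 0 or np.std(y) == 0:
            r2 = float("nan")
        else:
            r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        out[name] = {"rmse": rmse, "r2": r2}
    out["summary"] = {
        "dipole_rmse": float(np.mean([out[c]["rmse"]
                                      for c in DIPOLE_COMPONENTS])),
        "quadrupole_rmse": float(np.mean([out[c]["rmse"]
                                          for c in QUADRUPOLE_COMPONENTS])),
    }
    return out
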