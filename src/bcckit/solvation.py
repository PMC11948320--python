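"""Solvation free-energy error statistics, transfer free energy and logP.

Benchmark datasets pair an experimental solvation free energy (kcal/mol)
with a calculated one per solute-solvent record.  The error layer reports
the field's standard scorecard — mean signed error (MSE), mean unsigned
error (MUE), root-mean-square error (RMSE), Pearson's R and the Pearlman
predictive index (PI, a pairwise rank-agreement statistic weighted by
experimental differences) — plus error-band fractions, molecular-weight-
binned signed errors, and per-group summaries.

Transfer free energy between two solvents is the difference of solvation
free energies, dG_trans(a->b) = dG_solv,b - dG_solv,a, and converts
linearly to the partition coefficient: logP = -dG_trans / (R T ln 10).
The signed error convention is calculated minus experimental throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE",
    "SolvationRecord",
    "StatsSummary",
    "transfer_free_energy",
    "logp_from_transfer",
    "summary_stats",
    "pearlman_pi",
    "error_band_fractions",
    "binned_signed_error",
    "groupwise_stats",
    "read_solvation_table",
    "write_solvation_table",
]

#: ideal-gas constant, kcal/(mol*K)
GAS_CONSTANT_KCAL = 1.98720e-3

#: default temperature for logP conversion, K
DEFAULT_TEMPERATURE = 298.15


@dataclass(frozen=True)
class SolvationRecord:
    """One solute-solvent pair: experimental and calculated dG (kcal/mol)."""

    solute: str
    solvent: str
    dg_exp: float
    dg_calc: float
    uncertainty: float | None = None
    mw: float | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dg_exp) and math.isfinite(self.dg_calc)):
            raise ValueError("free energies must be finite")
        if self.uncertainty is not None and self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")

    @property
    def signed_error(self) -> float:
        """Calculated minus experimental, kcal/mol."""
        return self.dg_calc - self.dg_exp


@dataclass(frozen=True)
class StatsSummary:
    """n, MSE, MUE, RMSE (kcal/mol), PI and Pearson R for one record set."""

    n: int
    mse: float
    mue: float
    rmse: float
    pi: float | None
    r: float | None


def transfer_free_energy(dg_solv_a: float, dg_solv_b: float) -> float:
    """dG of transferring the solute from solvent a to solvent b."""
    return dg_solv_b - dg_solv_a


def logp_from_transfer(dg_trans: float,
                       temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Partition coefficient logP from a water->solvent transfer dG.

    logP = -dG_trans / (R T ln 10): a negative transfer free energy
    (solvation more favourable in the organic phase) gives a positive
    logP.  Linear, so any linear error statistic of dG_trans converts to
    log units by the same factor.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -dg_trans / (GAS_CONSTANT_KCAL * temperature * math.log(10.0))


def _errors(records: Sequence[SolvationRecord]) -> np.ndarray:
    return np.array([r.signed_error for r in records])


def pearlman_pi(exp: Sequence[float], calc: Sequence[float]) -> float | None:
    """Predictive index: weighted pairwise rank agreement in [-1, 1].

    Over all pairs i<j, weight w_ij = |exp_j - exp_i| and agreement
    c_ij = sign((calc_j - calc_i) (exp_j - exp_i)), with c_ij = 0 when the
    calculated difference is zero.  Pairs with equal experimental values
    carry zero weight; if every weight vanishes the index is undefined
    (None).
    """
    exp = np.asarray(exp, float)
    calc = np.asarray(calc, float)
    if exp.shape != calc.shape or exp.size < 2:
        raise ValueError("need matched experimental/calculated lists, n >= 2")
    de = exp[None, :] - exp[:, None]
    dc = calc[None, :] - calc[:, None]
    iu = np.triu_indices(exp.size, k=1)
    w = np.abs(de[iu])
    c = np.sign(dc[iu]) * np.sign(de[iu])
    denom = w.sum()
    if denom == 0:
        return None
    return float((w * c).sum() / denom)


def summary_stats(records: Sequence[SolvationRecord]) -> StatsSummary:
    """MSE / MUE / RMSE / PI / Pearson R for a record set.

    PI and R need n >= 2 (and non-constant series for R) and are reported
    as None otherwise.  The invariants RMSE >= MUE >= |MSE| hold by the
    triangle and Jensen inequalities.
    """
    if not records:
        raise ValueError("empty record set")
    err = _errors(records)
    exp = np.array([r.dg_exp for r in records])
    calc = np.array([r.dg_calc for r in records])
    pi = r = None
    if len(records) >= 2:
        pi = pearlman_pi(exp, calc)
        if np.std(exp) > 0 and np.std(calc) > 0:
            r = float(np.corrcoef(exp, calc)[0, 1])
    return StatsSummary(
        n=len(records),
        mse=float(err.mean()),
        mue=float(np.abs(err).mean()),
        rmse=float(np.sqrt((err ** 2).mean())),
        pi=pi,
        r=r,
    )


def error_band_fractions(records: Sequence[SolvationRecord],
                         thresholds: Sequence[float]) -> dict[float, float]:
    """Fraction of records with |calc - exp| < t for each threshold t."""
    thresholds = list(thresholds)
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    err = np.abs(_errors(records))
    return {t: float((err < t).mean()) for t in thresholds}


def binned_signed_error(records: Sequence[SolvationRecord],
                        bin_width: float = 25.0
                        ) -> pd.DataFrame:
    """Mean signed error per molecular-weight bin [k*w, (k+1)*w).

    Records without a molecular weight are skipped.  Empty bins are
    omitted.  Returns a frame with bin_left, bin_right, n, mean_se.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    rows = []
    for r in records:
        if r.mw is None:
            continue
        rows.append((math.floor(r.mw / bin_width), r.signed_error))
    if not rows:
        return pd.DataFrame(columns=["bin_left", "bin_right", "n", "mean_se"])
    df = pd.DataFrame(rows, columns=["bin", "se"])
    g = df.groupby("bin")["se"].agg(["size", "mean"]).reset_index()
    return pd.DataFrame({
        "bin_left": g["bin"] * bin_width,
        "bin_right": (g["bin"] + 1) * bin_width,
        "n": g["size"].astype(int),
        "mean_se": g["mean"],
    })


def groupwise_stats(records: Sequence[SolvationRecord],
                    min_group_size: int = 5
                    ) -> dict[str, tuple[StatsSummary, bool]]:
    """Per-group scorecards keyed by the records' group label.

    Each value is ``(summary, large_enough)`` where the flag marks groups
    meeting ``min_group_size`` (default 5).  Records without a label fall
    into the group ``"(unlabeled)"``.
    """
    groups: dict[str, list[SolvationRecord]] = {}
    for r in records:
        groups.setdefault(r.group or "(unlabeled)", []).append(r)
    return {
        label: (summary_stats(members), len(members) >= min_group_size)
        for label, members in sorted(groups.items())
    }


_REQUIRED_COLUMNS = ("solute", "solvent", "exp", "calc")


def read_solvation_table(source: str | Path | TextIO,
                         column_map: Mapping[str, str] | None = None,
                         ) -> tuple[list[SolvationRecord], list[int]]:
    """Read a delimited table of solvation records.

    ``column_map`` maps logical names (solute, solvent, exp, calc, and
    optionally uncertainty, mw, group) to the file's column headers;
    logical names themselves are the default.  The delimiter (comma or
    tab) is sniffed.  Rows that fail to parse are dropped; their 1-based
    line numbers are returned alongside the good records.
    """
    from .io import as_text

    text = as_text(source)
    import io as _io

    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(_io.StringIO(text), sep=sep, comment="#",
                     dtype=str, skip_blank_lines=True)
    cmap = {k: k for k in
            ("solute", "solvent", "exp", "calc", "uncertainty", "mw", "group")}
    if column_map:
        cmap.update(column_map)
    for logical in _REQUIRED_COLUMNS:
        if cmap[logical] not in df.columns:
            raise ValueError(
                f"required column {cmap[logical]!r} (for {logical}) missing"
            )
    records: list[SolvationRecord] = []
    rejected: list[int] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1

        def opt(logical: str, cast):
            col = cmap[logical]
            if col not in df.columns:
                return None
            val = row[col]
            if pd.isna(val) or str(val).strip() == "":
                return None
            return cast(val)

        try:
            records.append(SolvationRecord(
                solute=str(row[cmap["solute"]]),
                solvent=str(row[cmap["solvent"]]),
                dg_exp=float(row[cmap["exp"]]),
                dg_calc=float(row[cmap["calc"]]),
                uncertainty=opt("uncertainty", float),
                mw=opt("mw", float),
                group=opt("group", str),
            ))
        except (TypeError, ValueError):
            rejected.append(line_no)
    return records, rejected


def write_solvation_table(records: Iterable[SolvationRecord]) -> str:
    """Serialize records to TSV (inverse of read_solvation_table)."""
    lines = ["solute\tsolvent\texp\tcalc\tuncertainty\tmw\tgroup"]
    for r in records:
        lines.append("\t".join([
            r.solute, r.solvent, f"{r.dg_exp:.4f}", f"{r.dg_calc:.4f}",
            "" if r.uncertainty is None else f"{r.uncertainty:.4f}",
            "" if r.mw is None else f"{r.mw:.3f}",
            r.group or "",
        ]))
    return "\n".join(lines) + "\n"
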