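"""Peptide-level hydrogen/deuterium-exchange (HDX-MS) analysis.

Centroid masses per peptide and time point are converted to relative
deuterium uptake, aggregated into per-stretch exchange rates, mapped onto
residues, differenced between two conditions (e.g. mutant − wild type) and
painted onto structures via the B-factor column.

Conventions (the field uses several; these are pinned and configurable):

* exchangeable amides per peptide = length − 1 − internal prolines (the
  N-terminal amide back-exchanges too fast to observe; proline has none);
* relative uptake(t) = 100 · (m(t) − m0) / denominator, where the
  denominator is the fully-deuterated control mass difference when a
  control is available (back-exchange-corrected "normalized" rate), else
  max-exchangeable × labeling deuterium fraction (0.9 for a 10× dilution
  into deuterated buffer);
* the per-stretch "HDX rate" is the mean relative uptake over the sampled
  time course.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Structure
from .errors import AlphabetError, EmptyInputError, NormalizationError

__all__ = [
    "PeptideRecord",
    "max_exchangeable",
    "relative_uptake",
    "hdx_rate",
    "analyze_peptides",
    "residue_map",
    "difference_map",
    "color_structure",
    "read_peptide_table",
    "write_peptide_table",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Deuterium fraction of the labeling buffer after the standard 10x dilution.
DEFAULT_DEUTERIUM_FRACTION = 0.9

#: Sentinel B-factor for residues without HDX coverage.
UNCOVERED_SENTINEL = -1.0


@dataclass
class PeptideRecord:
    """One proteolytic peptide followed over the exchange time course."""

    sequence: str
    start: int
    end: int
    times: np.ndarray  # minutes, ascending
    masses: np.ndarray  # centroid masses (Da), parallel to times
    m0: float  # undeuterated centroid mass (Da)
    fd_control: float | None = None  # fully-deuterated control mass (Da)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.masses = np.asarray(self.masses, float)
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"peptide {self.start}-{self.end}: sequence length "
                f"{len(self.sequence)} != span {self.end - self.start + 1}"
            )
        if self.times.shape != self.masses.shape:
            raise ValueError("times and masses must be parallel")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time points must be strictly ascending")

    @property
    def length(self) -> int:
        return len(self.sequence)


def max_exchangeable(sequence: str) -> int:
    """Number of observable exchangeable backbone amides of a peptide.

    length − 1 (N-terminal amide excluded) − prolines after the first
    residue (no amide hydrogen).
    """
    if not sequence:
        raise AlphabetError("empty sequence")
    bad = set(sequence.upper()) - AMINO_ACIDS
    if bad:
        raise AlphabetError(f"unknown residue letters: {sorted(bad)}")
    seq = sequence.upper()
    return len(seq) - 1 - seq[1:].count("P")


def relative_uptake(
    record: PeptideRecord,
    deuterium_fraction: float = DEFAULT_DEUTERIUM_FRACTION,
) -> np.ndarray:
    """Relative uptake (%) at each time point.

    Denominator: fully-deuterated control (m_fd − m0) when available, else
    max_exchangeable × deuterium_fraction.
    """
    if record.fd_control is not None:
        denom = record.fd_control - record.m0
    else:
        denom = max_exchangeable(record.sequence) * deuterium_fraction
    if denom <= 0:
        raise NormalizationError(
            f"peptide {record.start}-{record.end}: non-positive denominator {denom}"
        )
    return 100.0 * (record.masses - record.m0) / denom


def hdx_rate(
    record: PeptideRecord,
    deuterium_fraction: float = DEFAULT_DEUTERIUM_FRACTION,
) -> float:
    """Per-stretch HDX rate (%): mean relative uptake over the time course."""
    if record.times.size < 2:
        raise EmptyInputError("need at least 2 time points for a rate")
    return float(relative_uptake(record, deuterium_fraction).mean())


def analyze_peptides(
    records: list[PeptideRecord],
    deuterium_fraction: float = DEFAULT_DEUTERIUM_FRACTION,
) -> pd.DataFrame:
    """Rates and per-time uptake for a peptide set, one row per peptide."""
    rows = []
    for r in records:
        rel = relative_uptake(r, deuterium_fraction)
        row = {
            "sequence": r.sequence,
            "start": r.start,
            "end": r.end,
            "max_exchangeable": max_exchangeable(r.sequence),
            "rate_percent": float(rel.mean()),
        }
        for t, u in zip(r.times, rel):
            row[f"uptake_t{t:g}"] = u
        rows.append(row)
    return pd.DataFrame(rows)


def residue_map(
    records: list[PeptideRecord],
    rates: list[float] | None = None,
    deuterium_fraction: float = DEFAULT_DEUTERIUM_FRACTION,
) -> dict[int, float]:
    """Per-residue rate (%): 1/length-weighted mean over covering peptides.

    Short peptides localize exchange better than long ones, hence the
    inverse-length weights.  Residues covered by no peptide are absent from
    the returned map.
    """
    if not records:
        raise EmptyInputError("no peptides")
    if rates is None:
        rates = [hdx_rate(r, deuterium_fraction) for r in records]
    num: dict[int, float] = {}
    den: dict[int, float] = {}
    for rec, rate in zip(records, rates):
        w = 1.0 / rec.length
        for resid in range(rec.start, rec.end + 1):
            num[resid] = num.get(resid, 0.0) + w * rate
            den[resid] = den.get(resid, 0.0) + w
    return {resid: num[resid] / den[resid] for resid in sorted(num)}


def difference_map(
    mutant: dict[int, float],
    wt: dict[int, float],
    tolerance: float = 5.0,
) -> pd.DataFrame:
    """Mutant − WT rate difference with rigidity classification.

    Residues covered in both maps get Δ = mutant − wt and a label:
    ``more_rigid`` (Δ < −tolerance), ``more_flexible`` (Δ > +tolerance),
    else ``unchanged``.
    """
    common = sorted(set(mutant) & set(wt))
    if not common:
        warnings.warn("difference_map: the two coverage sets do not overlap")
    rows = []
    for resid in common:
        delta = mutant[resid] - wt[resid]
        if delta < -tolerance:
            label = "more_rigid"
        elif delta > tolerance:
            label = "more_flexible"
        else:
            label = "unchanged"
        rows.append({"resid": resid, "delta_percent": delta, "classification": label})
    return pd.DataFrame(rows, columns=["resid", "delta_percent", "classification"])


def color_structure(
    structure: Structure,
    values: dict[int, float],
    sentinel: float = UNCOVERED_SENTINEL,
) -> Structure:
    """Copy of the structure with B-factors set to per-residue values.

    Residues absent from ``values`` get the sentinel, so viewers can mask
    uncovered regions.
    """
    out = structure.copy()
    for i in range(out.natoms):
        out.bfactor[i] = values.get(int(out.resid[i]), sentinel)
    return out


# ---------------------------------------------------------------------------
# TSV input/output
# ---------------------------------------------------------------------------

def write_peptide_table(records: list[PeptideRecord], path: str | Path) -> None:
    """TSV with columns sequence, start, end, m0[, fd] and one t<min> column
    per time point."""
    times = records[0].times
    rows = []
    for r in records:
        if not np.array_equal(r.times, times):
            raise ValueError("all peptides must share the same time points")
        row = {"sequence": r.sequence, "start": r.start, "end": r.end, "m0": r.m0}
        if r.fd_control is not None:
            row["fd"] = r.fd_control
        for t, m in zip(r.times, r.masses):
            row[f"t{t:g}"] = m
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_peptide_table(path: str | Path) -> list[PeptideRecord]:
    df = pd.read_csv(path, sep="\t")
    tcols = [c for c in df.columns if c.startswith("t") and c[1:].replace(".", "", 1).isdigit()]
    times = np.array(sorted(float(c[1:]) for c in tcols))
    records = []
    for _, row in df.iterrows():
        masses = np.array([row[f"t{t:g}"] for t in times], float)
        records.append(
            PeptideRecord(
                sequence=str(row["sequence"]),
                start=int(row["start"]),
                end=int(row["end"]),
                times=times,
                masses=masses,
                m0=float(row["m0"]),
                fd_control=float(row["fd"]) if "fd" in df.columns and pd.notna(row.get("fd")) else None,
            )
        )
    if not records:
        raise EmptyInputError(f"{path}: no peptides")
    return records
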