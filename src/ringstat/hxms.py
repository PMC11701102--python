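"""Hydrogen-deuterium exchange (HX-MS) protection statistics.

Peptide-level centroid masses from three measurements — an undeuterated
control (m0), the labelled sample (m_t) and a fully deuterated control
(m100) — give the back-exchange-corrected uptake fraction

    uptake = (m_t − m0) / (m100 − m0).

To compare a ligand-bound condition against baseline on regions with very
different intrinsic exchange, protection is expressed relative to the
fraction that still exchanges in the baseline condition:

    relative_exchange   = 100 · ligand / baseline      (%)
    relative_protection = 100 · (baseline − ligand) / baseline  (%)

so that full protection by the ligand scores 100 %.  Peptides whose
baseline exchange is below 10 % are flagged not-shown: on an already rigid
region the relative statistic is dominated by noise.

Per-residue consolidation averages relative_exchange over all shown
peptides covering a residue, for painting onto a structure via the
temperature-factor column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import StructureModel

__all__ = [
    "PeptideExchange",
    "ProtectionRecord",
    "BASELINE_SHOWN_THRESHOLD",
    "uptake_fraction",
    "exchange_percent",
    "protection_table",
    "apply_baseline_filter",
    "residue_consolidation",
    "read_peptide_table",
    "write_protection_table",
    "paint_structure",
]

#: minimum baseline exchange (%) for a peptide to be shown (inclusive)
BASELINE_SHOWN_THRESHOLD = 10.0


@dataclass(frozen=True)
class PeptideExchange:
    """Centroid masses (Da) of one peptide in one condition.

    ``start``/``end`` are 1-based inclusive residue numbers; ``charge`` lets
    several charge states of the same peptide coexist (they are averaged
    before scoring).
    """

    peptide_id: str
    start: int
    end: int
    condition: str  # {baseline, ligand}
    m0: float
    m_t: float
    m100: float
    sequence: str = ""
    charge: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"peptide {self.peptide_id}: start {self.start} > end {self.end}")
        if self.m100 <= self.m0:
            raise ValueError(
                f"peptide {self.peptide_id}: fully deuterated control mass "
                f"{self.m100} must exceed undeuterated mass {self.m0}"
            )

    @property
    def match_key(self) -> tuple[int, int, str]:
        return (self.start, self.end, self.sequence)


@dataclass(frozen=True)
class ProtectionRecord:
    """Per-peptide exchange percentages and the derived relative statistics."""

    peptide_id: str
    start: int
    end: int
    baseline_exchange: float  # %
    ligand_exchange: float  # %
    relative_exchange: float  # % of baseline; NaN when baseline is 0
    relative_protection: float  # 100 − relative_exchange
    shown: bool
    sequence: str = ""


def uptake_fraction(m_t: float, m0: float, m100: float) -> float:
    """Back-exchange-corrected uptake fraction, clamped to [0, 1]."""
    if m100 <= m0:
        raise ValueError(f"invalid controls: m100 ({m100}) must exceed m0 ({m0})")
    raw = (m_t - m0) / (m100 - m0)
    return min(max(raw, 0.0), 1.0)


def exchange_percent(p: PeptideExchange) -> float:
    return 100.0 * uptake_fraction(p.m_t, p.m0, p.m100)


def _mean_exchange_by_peptide(peptides: list[PeptideExchange]) -> dict[tuple, dict]:
    """Average charge states per peptide, then score the averaged masses."""
    groups: dict[tuple, list[PeptideExchange]] = {}
    for p in peptides:
        groups.setdefault(p.match_key, []).append(p)
    out: dict[tuple, dict] = {}
    for key, members in groups.items():
        m0 = float(np.mean([p.m0 for p in members]))
        m_t = float(np.mean([p.m_t for p in members]))
        m100 = float(np.mean([p.m100 for p in members]))
        out[key] = {
            "peptide_id": members[0].peptide_id,
            "start": members[0].start,
            "end": members[0].end,
            "sequence": members[0].sequence,
            "exchange": 100.0 * uptake_fraction(m_t, m0, m100),
        }
    return out


def protection_table(
    baseline: list[PeptideExchange],
    ligand: list[PeptideExchange],
) -> tuple[list[ProtectionRecord], list[tuple]]:
    """Score matched peptides; return (records, unmatched peptide keys).

    Peptides are matched across conditions by (start, end, sequence); a
    peptide must appear in both conditions to be scored.
    """
    base = _mean_exchange_by_peptide(baseline)
    lig = _mean_exchange_by_peptide(ligand)
    matched = [k for k in base if k in lig]
    unmatched = sorted(set(base) ^ set(lig))
    if not matched:
        raise ValueError("no peptides matched between baseline and ligand conditions")
    records = []
    for key in sorted(matched):
        b = base[key]["exchange"]
        l = lig[key]["exchange"]
        if b > 0:
            rel_ex = 100.0 * l / b
            rel_prot = 100.0 * (b - l) / b
        else:
            rel_ex = math.nan
            rel_prot = math.nan
        records.append(
            ProtectionRecord(
                peptide_id=base[key]["peptide_id"],
                start=base[key]["start"],
                end=base[key]["end"],
                sequence=base[key]["sequence"],
                baseline_exchange=b,
                ligand_exchange=l,
                relative_exchange=rel_ex,
                relative_protection=rel_prot,
                shown=b >= BASELINE_SHOWN_THRESHOLD,
            )
        )
    return records, unmatched


def apply_baseline_filter(
    records: list[ProtectionRecord],
    threshold: float = BASELINE_SHOWN_THRESHOLD,
) -> list[ProtectionRecord]:
    """Re-flag ``shown`` = (baseline_exchange ≥ threshold); nothing deleted."""
    return [replace(r, shown=r.baseline_exchange >= threshold) for r in records]


def residue_consolidation(
    records: list[ProtectionRecord],
    length: int,
) -> np.ndarray:
    """Mean relative_exchange per residue over the shown peptides covering it.

    Returns an array of ``length`` values indexed by residue number − 1;
    residues with no shown coverage are NaN.
    """
    shown = [r for r in records if r.shown and not math.isnan(r.relative_exchange)]
    if not shown:
        raise ValueError("no shown records to consolidate")
    total = np.zeros(length)
    count = np.zeros(length)
    for r in shown:
        lo = max(r.start, 1) - 1
        hi = min(r.end, length)
        total[lo:hi] += r.relative_exchange
        count[lo:hi] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return values


# ---------------------------------------------------------------------------
# tabular I/O

_COLUMNS = ["peptide_id", "start", "end", "sequence", "condition", "charge", "m0", "m_t", "m100"]


def read_peptide_table(path: str | Path) -> list[PeptideExchange]:
    """Read a TSV/CSV peptide centroid table (delimiter sniffed)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in ("peptide_id", "start", "end", "condition", "m0", "m_t", "m100")
               if c not in df.columns]
    if missing:
        raise ValueError(f"peptide table {path} lacks columns: {missing}")
    peptides = []
    for row in df.itertuples(index=False):
        seq = getattr(row, "sequence", "")
        if seq is None or (isinstance(seq, float) and math.isnan(seq)):
            seq = ""
        charge = getattr(row, "charge", 0)
        if charge is None or (isinstance(charge, float) and math.isnan(charge)):
            charge = 0
        peptides.append(
            PeptideExchange(
                peptide_id=str(row.peptide_id),
                start=int(row.start),
                end=int(row.end),
                condition=str(row.condition),
                m0=float(row.m0),
                m_t=float(row.m_t),
                m100=float(row.m100),
                sequence=str(seq),
                charge=int(charge),
            )
        )
    return peptides


def write_protection_table(records: list[ProtectionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "peptide_id": [r.peptide_id for r in records],
            "start": [r.start for r in records],
            "end": [r.end for r in records],
            "sequence": [r.sequence for r in records],
            "baseline_exchange": [r.baseline_exchange for r in records],
            "ligand_exchange": [r.ligand_exchange for r in records],
            "relative_exchange": [r.relative_exchange for r in records],
            "relative_protection": [r.relative_protection for r in records],
            "shown": [r.shown for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def paint_structure(
    model: StructureModel,
    per_residue: np.ndarray,
    chain_id: str | None = None,
    missing_value: float = -1.0,
) -> StructureModel:
    """Copy per-residue values into the temperature-factor field.

    Residue i (1-based) receives ``per_residue[i-1]``; residues outside the
    array or without coverage get ``missing_value``.  Use with
    :func:`ringstat.structure_io.write_structure` for structure colouring.
    """
    atoms = []
    for a in model.atoms:
        if chain_id is not None and a.chain_id != chain_id:
            atoms.append(a)
            continue
        idx = a.residue_number - 1
        if 0 <= idx < len(per_residue) and not math.isnan(per_residue[idx]):
            value = float(per_residue[idx])
        else:
            value = missing_value
        atoms.append(replace(a, b_factor=value))
    return model.with_atoms(atoms)
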