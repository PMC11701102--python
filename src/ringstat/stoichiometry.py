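"""Molar stoichiometry from gel-band densitometry.

Coomassie band intensity scales with protein mass loaded, so dividing each
band's intensity by the protein's molecular weight gives a quantity
proportional to molar amount.  Ratios to a reference subunit are computed
within each replicate (cancelling lane-level scale factors) and summarised
as mean ± sample SD across replicates.

Molecular weights are user-supplied construct masses in kDa: tagged
constructs (His-, FLAG-) differ from database masses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["BandMeasurement", "MolarRatioReport", "molar_ratios", "read_band_table"]


@dataclass(frozen=True)
class BandMeasurement:
    """One gel band: densitometry intensity and construct MW (kDa)."""

    protein: str
    intensity: float  # arbitrary units, >= 0
    molecular_weight: float  # kDa, > 0
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"{self.protein}: intensity must be non-negative")
        if self.molecular_weight <= 0:
            raise ValueError(f"{self.protein}: molecular weight must be positive")


@dataclass(frozen=True)
class MolarRatioReport:
    """Per-protein molar ratio to the reference, mean ± SD over replicates."""

    reference: str
    ratios: dict[str, tuple[float, float]]  # protein -> (mean, sd)
    n_replicates: int

    def mean(self, protein: str) -> float:
        return self.ratios[protein][0]

    def sd(self, protein: str) -> float:
        return self.ratios[protein][1]


def molar_ratios(bands: list[BandMeasurement], reference: str) -> MolarRatioReport:
    """MW-normalised molar ratios relative to ``reference``.

    Within each replicate, ratio_i = (I_i / MW_i) / (I_ref / MW_ref); the
    report is mean ± sample SD (ddof=1) across replicates.  The reference
    protein must be present with positive intensity in every replicate.
    """
    if not bands:
        raise ValueError("no band measurements supplied")
    by_rep: dict[int, list[BandMeasurement]] = {}
    for b in bands:
        by_rep.setdefault(b.replicate, []).append(b)
    per_protein: dict[str, list[float]] = {}
    for rep, members in sorted(by_rep.items()):
        ref = [b for b in members if b.protein == reference]
        if not ref or ref[0].intensity <= 0:
            raise ValueError(
                f"reference protein {reference!r} missing or zero-intensity in replicate {rep}"
            )
        ref_molar = ref[0].intensity / ref[0].molecular_weight
        for b in members:
            per_protein.setdefault(b.protein, []).append(
                (b.intensity / b.molecular_weight) / ref_molar
            )
    ratios = {}
    for protein, values in per_protein.items():
        arr = np.asarray(values)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        ratios[protein] = (float(arr.mean()), sd)
    return MolarRatioReport(reference=reference, ratios=ratios, n_replicates=len(by_rep))


def read_band_table(path: str | Path) -> list[BandMeasurement]:
    """Read a TSV/CSV with columns protein, replicate, intensity, mw_kda."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in ("protein", "replicate", "intensity", "mw_kda") if c not in df.columns]
    if missing:
        raise ValueError(f"band table {path} lacks columns: {missing}")
    return [
        BandMeasurement(
            protein=str(row.protein),
            intensity=float(row.intensity),
            molecular_weight=float(row.mw_kda),
            replicate=int(row.replicate),
        )
        for row in df.itertuples(index=False)
    ]
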