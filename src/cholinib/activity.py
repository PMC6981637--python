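"""Activity analytics: selectivity index, IC50 -> binding free energy, Lipinski screen.

The selectivity index (SI) is defined as IC50(BChE)/IC50(AChE): values above 1
mean AChE-selective, below 1 BChE-selective.  IC50 values are converted to an
experimental binding free energy via the Cheng-Prusoff-style approximation
Ki ~ IC50, so dG = R*T*ln(IC50) with IC50 in molar units — more negative means
more potent.  Only relative ordering of dG matters downstream (the consensus
fit is affine-invariant), so the approximation is benign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "R_KCAL",
    "STANDARD_T",
    "InhibitionResult",
    "FreeEnergy",
    "DescriptorRow",
    "selectivity_index",
    "ic50_to_dg",
    "rule_of_five",
    "load_activity",
    "dg_table",
]

#: Gas constant in kcal/(mol*K).
R_KCAL = 1.987e-3
#: Default assay temperature (K).
STANDARD_T = 298.15


@dataclass(frozen=True)
class InhibitionResult:
    compound: str
    target: str  # "AChE" | "BChE"
    ic50_uM: float
    sem_uM: float | None = None

    def __post_init__(self):
        if self.target not in ("AChE", "BChE"):
            raise ValueError(f"target must be AChE or BChE, got {self.target!r}")
        if not self.ic50_uM > 0:
            raise ValueError("IC50 must be positive")


@dataclass(frozen=True)
class FreeEnergy:
    dg: float  # kcal/mol
    temperature: float = STANDARD_T

    def __post_init__(self):
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class DescriptorRow:
    """Predicted descriptors used by the rule-of-five screen (inputs, not computed)."""

    compound: str
    mw: float
    logp: float
    hb_donors: int
    hb_acceptors: float

    def __post_init__(self):
        if self.hb_donors < 0 or self.hb_acceptors < 0:
            raise ValueError("H-bond counts must be non-negative")


def selectivity_index(ic50_bche_uM: float, ic50_ache_uM: float) -> float:
    """SI = IC50(BChE) / IC50(AChE); > 1 means AChE-selective."""
    if ic50_bche_uM <= 0 or ic50_ache_uM <= 0:
        raise ValueError("IC50 values must be positive")
    return ic50_bche_uM / ic50_ache_uM


def ic50_to_dg(ic50_molar: float, temperature: float = STANDARD_T) -> FreeEnergy:
    """Experimental binding free energy dG = R*T*ln(IC50), IC50 in mol/L."""
    if ic50_molar <= 0:
        raise ValueError("IC50 must be positive")
    return FreeEnergy(dg=R_KCAL * temperature * math.log(ic50_molar), temperature=temperature)


def rule_of_five(row: DescriptorRow) -> list[str]:
    """Lipinski violations, strict inequalities; empty list means compliant."""
    flags = []
    if row.mw > 500:
        flags.append("MW>500")
    if row.logp > 5:
        flags.append("logP>5")
    if row.hb_donors > 5:
        flags.append("HBD>5")
    if row.hb_acceptors > 10:
        flags.append("HBA>10")
    return flags


def load_activity(path=None) -> list[InhibitionResult]:
    """Load the packaged activity table (printed IC50s only; nothing imputed)."""
    src = path if path is not None else resources.files("cholinib.data").joinpath("activity.csv")
    df = pd.read_csv(src)
    if "sem_uM" not in df.columns:
        df["sem_uM"] = float("nan")
    return [
        InhibitionResult(
            compound=r.compound,
            target=r.target,
            ic50_uM=float(r.ic50_uM),
            sem_uM=None if pd.isna(r.sem_uM) else float(r.sem_uM),
        )
        for r in df.itertuples(index=False)
    ]


def dg_table(
    results: list[InhibitionResult],
    target: str = "AChE",
    temperature: float = STANDARD_T,
) -> dict[str, float]:
    """Map compound -> dGexpt (kcal/mol) for one enzyme target."""
    return {
        r.compound: ic50_to_dg(r.ic50_uM * 1e-6, temperature).dg
        for r in results
        if r.target == target
    }
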