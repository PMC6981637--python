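"""Compound registry and molecular-formula mass calculus.

The registry is a transcription of the 44 tetrahydroquinoline (THQ)
isoxazoline/isoxazole hybrids of the study series: 16 THQ-isoxazoline
compounds (series 5, two stereocenters) and 28 THQ-isoxazole compounds
(series 6, one stereocenter), each with its molecular formula, the
substituent at THQ C-6 (and C-8 for the four 8'-chloro compounds), the C-3
aryl pattern, yield, and physical state.  It is shipped as a plain CSV data
table; this module supplies the formula arithmetic that reproduces the
calculated analytical numbers: average molecular weight, monoisotopic mass,
elemental percentages, and ESI adduct m/z values.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .masses import ALLOWED_ELEMENTS, AVERAGE_WEIGHT, MONOISOTOPIC_MASS

__all__ = [
    "MolecularFormula",
    "CompoundRecord",
    "parse_formula",
    "average_mass",
    "monoisotopic_mass",
    "elemental_percentages",
    "adduct_mz",
    "count_stereoisomers",
    "load_registry",
    "load_known_discrepancies",
]

# Hill order: C first, H second, remaining elements alphabetical.
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map with Hill-order display.

    Counts are strictly positive; element symbols are restricted to the
    small set the chemotype needs (C, H, N, O, F, Cl, Br, Na, K, S).
    """

    counts: Mapping[str, int]

    def __post_init__(self):
        counts = dict(self.counts)
        for el, n in counts.items():
            if el not in ALLOWED_ELEMENTS:
                raise ValueError(f"unknown element symbol: {el!r}")
            if not isinstance(n, int) or n < 1:
                raise ValueError(f"count for {el} must be a positive integer, got {n!r}")
        object.__setattr__(self, "counts", counts)

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return MolecularFormula(dict(merged))

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        if not other.is_subformula_of(self):
            raise ValueError(f"{other} is not a sub-formula of {self}")
        left = Counter(self.counts)
        left.subtract(other.counts)
        return MolecularFormula({el: n for el, n in left.items() if n > 0})

    def __mul__(self, n: int) -> "MolecularFormula":
        return MolecularFormula({el: c * n for el, c in self.counts.items()})

    def is_subformula_of(self, other: "MolecularFormula") -> bool:
        return all(other[el] >= n for el, n in self.counts.items())

    def hill(self) -> str:
        """Display string in Hill order (C, H, then alphabetical)."""
        order = [el for el in ("C", "H") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H"))
        return "".join(f"{el}{self.counts[el] if self.counts[el] > 1 else ''}" for el in order)

    def __str__(self) -> str:
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a concatenated formula string such as ``"C23H25N3O2"``.

    An omitted count means 1.  Unknown element symbols, zero/negative counts
    and empty strings are rejected.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    pos = 0
    counts: Counter[str] = Counter()
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"unparseable formula text at {text[pos:]!r}")
        if not m.group(0):
            break
        el, digits = m.group(1), m.group(2)
        if el not in ALLOWED_ELEMENTS:
            raise ValueError(f"unknown element symbol: {el!r} in {text!r}")
        n = int(digits) if digits else 1
        if n < 1:
            raise ValueError(f"count for {el} must be >= 1, got {n}")
        counts[el] += n
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"unparseable formula text at {text[pos:]!r}")
    return MolecularFormula(dict(counts))


def average_mass(f: MolecularFormula) -> float:
    """Average molecular weight in g/mol (IUPAC standard atomic weights)."""
    return sum(n * AVERAGE_WEIGHT[el] for el, n in f.counts.items())


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Monoisotopic (principal-isotope exact) mass in Da."""
    return sum(n * MONOISOTOPIC_MASS[el] for el, n in f.counts.items())


def elemental_percentages(f: MolecularFormula) -> dict[str, float]:
    """Mass percentage of each element, as in elemental ("Anal. Calcd.") analysis."""
    total = average_mass(f)
    return {el: 100.0 * n * AVERAGE_WEIGHT[el] / total for el, n in f.counts.items()}


# Recognized ESI adduct forms. "[M-X+H]+" takes a neutral-loss fragment X.
_ADDUCT = re.compile(r"^\[(?P<n>\d*)M(?P<loss>-X)?\+(?P<cation>H|Na|K)\]\+$")


def adduct_mz(
    f: MolecularFormula,
    adduct: str,
    fragment: MolecularFormula | None = None,
) -> tuple[int, float]:
    """Nominal (integer) and exact m/z of an ESI adduct of ``f``.

    ``adduct`` is one of ``"[M+H]+"``, ``"[M+Na]+"``, ``"[M+K]+"``,
    ``"[2M+Na]+"`` ... or ``"[M-X+H]+"`` with ``fragment`` giving the neutral
    loss X (which must be a sub-formula of ``f``).  The electron mass is
    neglected (~0.0005 Da, below display precision).
    """
    m = _ADDUCT.match(adduct.replace(" ", "").replace("−", "-"))
    if not m:
        raise ValueError(f"unrecognized adduct spec: {adduct!r}")
    n = int(m.group("n")) if m.group("n") else 1
    exact = n * monoisotopic_mass(f)
    if m.group("loss"):
        if fragment is None:
            raise ValueError("loss adduct [M-X+H]+ requires a fragment formula")
        if not fragment.is_subformula_of(f):
            raise ValueError(f"fragment {fragment} is not a sub-formula of {f}")
        exact -= monoisotopic_mass(fragment)
    exact += MONOISOTOPIC_MASS[m.group("cation")]
    return round(exact), exact


@dataclass(frozen=True)
class CompoundRecord:
    """One registry row: identity, substituent grid, formula, bookkeeping."""

    id: str
    series: int  # 5 (isoxazoline, 2 stereocenters) or 6 (isoxazole, 1)
    r1_c6: str  # substituent at THQ C-6
    r5_c8: str  # substituent at THQ C-8 (Cl only for the 8'-chloro compounds)
    aryl: str  # C-3 aryl pattern: phenyl | 4-OMe | 3,4-diOMe | 3,4,5-triOMe
    formula: MolecularFormula
    n_stereocenters: int
    yield_pct: float
    state: str
    esi_mh: float | None = None  # printed [M+H]+ m/z, where reported

    def n_stereoisomers(self) -> int:
        # No meso forms arise in this chemotype: independent centers.
        return 2 ** self.n_stereocenters


def _data_path(name: str):
    return resources.files("cholinib.data").joinpath(name)


def load_registry(path=None) -> list[CompoundRecord]:
    """Load the packaged 44-compound registry (or a user CSV with its layout)."""
    src = path if path is not None else _data_path("registry.csv")
    df = pd.read_csv(src, dtype={"esi_mh": float})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CompoundRecord(
                id=row.id,
                series=int(row.series),
                r1_c6=row.r1_c6,
                r5_c8=row.r5_c8,
                aryl=row.aryl,
                formula=parse_formula(row.formula),
                n_stereocenters=int(row.n_stereocenters),
                yield_pct=float(row.yield_pct),
                state=row.state,
                esi_mh=None if pd.isna(row.esi_mh) else float(row.esi_mh),
            )
        )
    return records


def load_known_discrepancies(path=None) -> pd.DataFrame:
    """Transcription notes: printed values inconsistent with exact arithmetic."""
    src = path if path is not None else _data_path("known_discrepancies.csv")
    return pd.read_csv(src)


def count_stereoisomers(records: Iterable[CompoundRecord]) -> tuple[dict[str, int], int]:
    """Per-record and total stereoisomer counts (docking input enumeration)."""
    per = {r.id: r.n_stereoisomers() for r in records}
    return per, sum(per.values())
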