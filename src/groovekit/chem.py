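"""Small-molecule arithmetic: formula masses, concentration conversion, m/z.

Covers the bookkeeping around a drug like nevirapine (C15H14N4O):
converting an assay's mass concentration to molarity and predicting the
singly protonated precursor ion for an LC-MS/MS transition. Atomic masses
are pinned in-code (IUPAC 2021 standard atomic weights and principal-
isotope monoisotopic masses) so the arithmetic is bit-stable everywhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from collections import Counter

__all__ = [
    "MolecularFormula",
    "molar_mass",
    "mass_conc_to_molar",
    "protonated_mz",
    "NEVIRAPINE",
    "PROTON_MASS",
]

#: Mass of a proton, Da (for [M+H]+ ions).
PROTON_MASS = 1.00728

# element -> (average atomic weight, monoisotopic principal-isotope mass)
_ATOMIC_MASS: dict[str, tuple[float, float]] = {
    "H": (1.008, 1.007825),
    "C": (12.011, 12.000000),
    "N": (14.007, 14.003074),
    "O": (15.999, 15.994915),
    "F": (18.998403, 18.998403),
    "Na": (22.989769, 22.989769),
    "P": (30.973762, 30.973762),
    "S": (32.06, 31.972071),
    "Cl": (35.45, 34.968853),
    "K": (39.0983, 38.963706),
    "Br": (79.904, 78.918338),
    "I": (126.90447, 126.904473),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """An element → count mapping, e.g. ``C15 H14 N4 O1`` for nevirapine."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("formula must contain at least one atom")
        for el, n in self.counts:
            if el not in _ATOMIC_MASS:
                raise ValueError(f"unknown element symbol {el!r}")
            if n < 1:
                raise ValueError(f"element count must be positive, got {el}{n}")

    @classmethod
    def parse(cls, formula: str) -> "MolecularFormula":
        """Parse a Hill-style formula string like ``"C15H14N4O"``."""
        stripped = formula.replace(" ", "")
        consumed = 0
        counts: Counter[str] = Counter()
        for m in _FORMULA_TOKEN.finditer(stripped):
            if not m.group(0):
                continue
            counts[m.group(1)] += int(m.group(2) or 1)
            consumed += len(m.group(0))
        if consumed != len(stripped) or not counts:
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(counts=tuple(sorted(counts.items())))

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = Counter(dict(self.counts)) + Counter(dict(other.counts))
        return MolecularFormula(counts=tuple(sorted(merged.items())))

    def __str__(self) -> str:
        return "".join(f"{el}{n if n > 1 else ''}" for el, n in self.counts)


def _as_formula(f) -> MolecularFormula:
    return f if isinstance(f, MolecularFormula) else MolecularFormula.parse(str(f))


def molar_mass(f, kind: str = "average") -> float:
    """Molar mass in g/mol (``kind="average"``) or Da (``"monoisotopic"``)."""
    if kind not in ("average", "monoisotopic"):
        raise ValueError(f"kind must be 'average' or 'monoisotopic', got {kind!r}")
    col = 0 if kind == "average" else 1
    return sum(_ATOMIC_MASS[el][col] * n for el, n in _as_formula(f).counts)


def mass_conc_to_molar(conc_ug_per_ml: float, f) -> float:
    """Convert a mass concentration (μg/mL) to molarity (μM).

    100 μg/mL of nevirapine (average molar mass 266.30 g/mol) is 375.5 μM.
    """
    if conc_ug_per_ml < 0:
        raise ValueError("concentration must be non-negative")
    return conc_ug_per_ml / molar_mass(f, "average") * 1000.0


def protonated_mz(f) -> float:
    """m/z of the singly protonated ion [M+H]+ (monoisotopic)."""
    return molar_mass(f, "monoisotopic") + PROTON_MASS


#: Nevirapine, the NNRTI whose HLA interaction this toolkit analyses.
NEVIRAPINE = MolecularFormula.parse("C15H14N4O")
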