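"""Molecular-formula arithmetic for herbal-component tables.

Component databases and LC-MS reports describe each compound by a Hill-style
molecular formula, an average molecular weight, and (for MS identification)
the m/z of a protonated [M+H]+ or deprotonated [M-H]- adduct.  This module
parses the formula strings as they appear in such tables (including
underscore/markup subscripts and a trailing charge sign), computes average or
monoisotopic mass from a built-in standard-atomic-weight table, and performs
the adduct m/z arithmetic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "Formula",
    "parse_formula",
    "average_mass",
    "monoisotopic_mass",
    "adduct_mz",
    "check_ion_consistency",
    "PROTON_MASS",
]

#: Mass of a proton in Da; the m/z shift of [M+H]+ / [M-H]- ions.
PROTON_MASS = 1.00728

# IUPAC standard (abridged) atomic weights, Da.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "Mg": 24.305, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "K": 39.098, "Ca": 40.078, "Mn": 54.938,
    "Fe": 55.845, "Cu": 63.546, "Zn": 65.38, "Se": 78.971, "Br": 79.904,
    "I": 126.904,
}

# Monoisotopic masses of the most abundant isotope, Da.
MONOISOTOPIC_MASSES: dict[str, float] = {
    "H": 1.0078250319, "B": 11.0093054, "C": 12.0, "N": 14.0030740052,
    "O": 15.9949146221, "F": 18.9984031627, "Na": 22.9897692820,
    "Mg": 23.9850417, "Si": 27.9769265347, "P": 30.97376151,
    "S": 31.97207069, "Cl": 34.96885271, "K": 38.9637064864,
    "Ca": 39.9625909, "Mn": 54.9380451, "Fe": 55.9349421,
    "Cu": 62.9296011, "Zn": 63.9291466, "Se": 79.9165218,
    "Br": 78.9183376, "I": 126.904473,
}

# Unicode sub/superscript digits occasionally found in extracted table text.
_SUBSCRIPT_MAP = str.maketrans("₀₁₂₃₄₅₆₇₈₉⁰¹²³⁴⁵⁶⁷⁸⁹", "01234567890123456789")

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """An elemental composition plus net charge.

    ``counts`` maps element symbol to a positive atom count; ``charge`` is
    the net charge implied by trailing ``+``/``-`` signs (e.g. quaternary
    alkaloids such as berberine are printed with a ``+`` suffix).
    """

    counts: tuple[tuple[str, int], ...]
    charge: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> int:
        return self.as_dict().get(element, 0)

    def hill_string(self) -> str:
        """Canonical Hill-order rendering: C, H, then other elements A-Z."""
        d = self.as_dict()
        parts: list[str] = []
        for el in ("C", "H"):
            if el in d:
                parts.append(el + (str(d[el]) if d[el] != 1 else ""))
        for el in sorted(k for k in d if k not in ("C", "H")):
            parts.append(el + (str(d[el]) if d[el] != 1 else ""))
        if self.charge > 0:
            parts.append("+" * self.charge)
        elif self.charge < 0:
            parts.append("-" * (-self.charge))
        return "".join(parts)


def parse_formula(text: str) -> Formula:
    """Parse a molecular-formula string into a :class:`Formula`.

    Tolerates the markup found in extracted tables: underscore-wrapped
    subscripts (``C_8_H_8_O_4_``), unicode subscript digits, whitespace, and
    a trailing charge suffix (``+``, ``^+^``).

    Raises
    ------
    ValueError
        If the string is empty, contains an unknown element symbol, or has
        leftover unparseable characters.
    """
    if text is None or not str(text).strip():
        raise ValueError("empty molecular formula")
    s = str(text).translate(_SUBSCRIPT_MAP)
    s = re.sub(r"[\s_^]", "", s)
    charge = s.count("+") - s.count("-")
    s = s.replace("+", "").replace("-", "")

    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN_RE.finditer(s):
        if m.start() != pos or not m.group(0):
            break
        el, num = m.group(1), m.group(2)
        if el not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element symbol {el!r} in formula {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(s) or not counts:
        raise ValueError(f"cannot parse molecular formula {text!r}")
    return Formula(counts=tuple(counts.items()), charge=charge)


def _mass(f: Formula | str, table: dict[str, float]) -> float:
    if isinstance(f, str):
        f = parse_formula(f)
    return sum(table[el] * n for el, n in f.counts)


def average_mass(f: Formula | str) -> float:
    """Average molecular weight in Da (sum of standard atomic weights)."""
    return _mass(f, ATOMIC_WEIGHTS)


def monoisotopic_mass(f: Formula | str) -> float:
    """Monoisotopic mass in Da (most-abundant-isotope masses)."""
    return _mass(f, MONOISOTOPIC_MASSES)


def adduct_mz(mw: float, ion: str) -> float:
    """m/z of a singly charged protonation adduct.

    ``M+H`` gives mw + proton mass, ``M-H`` gives mw - proton mass.  Ion
    labels are matched case-insensitively and tolerate a unicode minus.
    """
    if not mw > 0:
        raise ValueError(f"molecular weight must be positive, got {mw}")
    label = str(ion).strip().upper().replace("−", "-").replace(" ", "")
    if label in ("M+H", "[M+H]+"):
        return mw + PROTON_MASS
    if label in ("M-H", "[M-H]-"):
        return mw - PROTON_MASS
    raise ValueError(f"unknown ion label {ion!r}; expected 'M+H' or 'M-H'")


def check_ion_consistency(mw: float, mz: float, ion: str, tol: float = 0.05) -> bool:
    """Whether a reported (MW, m/z, ion-label) triple is arithmetically consistent.

    Published MS tables occasionally carry a positive-mode shift under a
    negative-mode label (or vice versa); such rows are flagged (returns
    False) rather than silently corrected.
    """
    return abs(adduct_mz(mw, ion) - mz) <= tol
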