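"""Exact-mass arithmetic for negative-ion ESI annotation.

Every matching decision in the rule engine reduces to monoisotopic-mass
bookkeeping: the mass of an elemental formula, the m/z of its deprotonated
([M-H]-) or proton-bound dimeric ([2M-H]-) ion, the mass of a neutral loss,
and ppm-scale error/window arithmetic for extracted-ion matching.

Conventions
-----------
* Singly deprotonated anions only: ion m/z = neutral monoisotopic mass minus
  the proton mass (1.00727646 Da).  No separate electron-mass bookkeeping --
  this reproduces standard printed calculated values (e.g. 781.1622 for
  C37H33O19-) at the fourth decimal place.
* Display rounding is round-half-up at the requested number of decimals,
  matching how calculated m/z values are conventionally printed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "Formula",
    "MassWindow",
    "monoisotopic_mass",
    "deprotonated_mz",
    "dimer_mz",
    "ppm_window",
    "ppm_error",
    "neutral_loss",
    "identify_loss",
    "round_half_up",
]

#: Monoisotopic atomic masses (Da), CODATA/IUPAC standard values.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

#: Mass of a proton (Da); [M-H]- m/z = M - PROTON_MASS.
PROTON_MASS = 1.00727646688

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparseable or chemically invalid formulas."""


@dataclass(frozen=True)
class Formula:
    """An elemental formula as non-negative element counts.

    Accepts Hill-notation strings; underscores are stripped so typeset
    variants like ``C_16_H_18_O_9_`` parse identically to ``C16H18O9``.
    """

    counts: tuple[tuple[str, int], ...]

    def __init__(self, formula: "str | Mapping[str, int] | Formula" = ""):
        if isinstance(formula, Formula):
            counts = dict(formula.counts)
        elif isinstance(formula, str):
            counts = _parse(formula)
        else:
            counts = {str(k): int(v) for k, v in formula.items()}
        for el, n in counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {el}: {n}")
        counts = {el: n for el, n in counts.items() if n > 0}
        object.__setattr__(
            self, "counts", tuple(sorted(counts.items()))
        )

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for el, n in Formula(other).counts:
            merged[el] = merged.get(el, 0) + n
        return Formula(merged)

    def __mul__(self, k: int) -> "Formula":
        return Formula({el: n * k for el, n in self.counts})

    __rmul__ = __mul__

    def __str__(self) -> str:  # Hill order: C, H, then alphabetical
        d = dict(self.counts)
        parts = []
        for el in ("C", "H"):
            if el in d:
                n = d.pop(el)
                parts.append(el if n == 1 else f"{el}{n}")
        for el in sorted(d):
            n = d[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def _parse(text: str) -> dict[str, int]:
    s = text.replace("_", "").replace(" ", "")
    if not s:
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(s):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at {s[pos:]!r}")
        if not m.group(0):
            break
        el, num = m.group(1), m.group(2)
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(s):
        raise FormulaError(f"cannot parse formula {text!r} at {s[pos:]!r}")
    return counts


FormulaLike = "str | Mapping[str, int] | Formula"


def monoisotopic_mass(formula) -> float:
    """Monoisotopic mass (Da) of a neutral formula; empty formula -> 0."""
    f = Formula(formula)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f.counts)


def _require_hydrogen(f: Formula, what: str) -> None:
    if f["H"] < 1:
        raise FormulaError(
            f"{what} requires at least one hydrogen to remove; got {f or 'empty formula'}"
        )


def deprotonated_mz(formula) -> float:
    """m/z of the [M-H]- ion of a neutral formula."""
    f = Formula(formula)
    _require_hydrogen(f, "[M-H]-")
    return monoisotopic_mass(f) - PROTON_MASS


def dimer_mz(formula) -> float:
    """m/z of the proton-bound dimeric [2M-H]- ion."""
    f = Formula(formula)
    _require_hydrogen(f, "[2M-H]-")
    return 2.0 * monoisotopic_mass(f) - PROTON_MASS


@dataclass(frozen=True)
class MassWindow:
    """A symmetric-in-ppm m/z interval used for extracted-ion matching."""

    lower: float
    upper: float

    def __post_init__(self):
        if not (0 < self.lower <= self.upper):
            raise ValueError(
                f"invalid mass window [{self.lower}, {self.upper}]"
            )

    def __contains__(self, mz: float) -> bool:
        return self.lower <= mz <= self.upper

    @property
    def center(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def width(self) -> float:
        return self.upper - self.lower


def ppm_window(center: float, tolerance_ppm: float) -> MassWindow:
    """The [c*(1 - t*1e-6), c*(1 + t*1e-6)] window around ``center``."""
    if center <= 0:
        raise ValueError(f"window center must be positive, got {center}")
    if tolerance_ppm < 0:
        raise ValueError(f"ppm tolerance must be >= 0, got {tolerance_ppm}")
    t = tolerance_ppm * 1e-6
    return MassWindow(center * (1.0 - t), center * (1.0 + t))


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(
            f"theoretical m/z must be positive, got {theoretical}"
        )
    return (measured - theoretical) / theoretical * 1e6


def neutral_loss(precursor_mz: float, fragment_mz: float) -> float:
    """Mass difference (Da) between a precursor and one of its fragments."""
    if fragment_mz >= precursor_mz:
        raise ValueError(
            f"fragment m/z {fragment_mz} must lie below precursor m/z {precursor_mz}"
        )
    return precursor_mz - fragment_mz


def identify_loss(
    delta: float,
    registry: Mapping[str, float] | Iterable[tuple[str, float]],
    tolerance: float = 0.01,
) -> str | None:
    """Name the registry residue whose loss mass matches ``delta``.

    ``registry`` maps residue name -> neutral-loss mass (Da).  Returns the
    in-tolerance name with the smallest absolute error, or None.
    """
    items = registry.items() if isinstance(registry, Mapping) else registry
    best, best_err = None, tolerance
    for name, mass in items:
        err = abs(delta - mass)
        if err <= best_err:
            best, best_err = name, err
    return best


def round_half_up(value: float, decimals: int) -> float:
    """Round-half-up at ``decimals`` places (display convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
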