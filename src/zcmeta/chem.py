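"""Elemental-composition arithmetic and the average carbon oxidation state.

The central quantity is the average oxidation state of carbon,

    Z_C = (-h + 3n + 2o + 2s) / c

for a chemical formula C_c H_h N_n O_o S_s.  Phosphorus and formal charge
are carried on :class:`ElementalComposition` for thermodynamic bookkeeping
(the nominal-oxidation-state generalisation sets both to zero for the
molecules treated here) but are excluded from Z_C by construction: the
phosphate backbone of a nucleic acid is attached by a dehydration reaction
and contains no C-P bonds, so Z_C of a strand of DNA or RNA equals that of
its constituent nucleosides.

Element counts are real numbers, not integers, so that average per-monomer
formulas such as C2.5H6NO2 (a 50/50 Ala/Gly protein) are first-class values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

__all__ = [
    "ElementalComposition",
    "WATER",
    "zc",
    "nosc",
    "combine",
    "dehydrate",
    "parse_formula",
]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d+(?:\.\d+)?|\.\d+)?")
_CHARGE = re.compile(r"([+-])(\d+)?\s*$")

_FIELD_BY_SYMBOL = {"C": "c", "H": "h", "N": "n", "O": "o", "S": "s", "P": "p"}


@dataclass(frozen=True)
class ElementalComposition:
    """Counts of C, H, N, O, S, P plus formal charge ``z``.

    Supports addition and scalar multiplication, which together make the
    weighted averaging used for per-monomer formulas a one-liner.
    """

    c: float = 0.0
    h: float = 0.0
    n: float = 0.0
    o: float = 0.0
    s: float = 0.0
    p: float = 0.0
    z: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s", "p"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative element count {name}={getattr(self, name)}")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        if not isinstance(other, ElementalComposition):
            return NotImplemented
        return ElementalComposition(
            self.c + other.c, self.h + other.h, self.n + other.n,
            self.o + other.o, self.s + other.s, self.p + other.p, self.z + other.z,
        )

    def __mul__(self, w: float) -> "ElementalComposition":
        if not isinstance(w, (int, float)):
            return NotImplemented
        if w < 0:
            raise ValueError("negative weight")
        return ElementalComposition(
            self.c * w, self.h * w, self.n * w, self.o * w,
            self.s * w, self.p * w, self.z * w,
        )

    __rmul__ = __mul__

    def as_tuple(self) -> Tuple[float, float, float, float, float, float, float]:
        return (self.c, self.h, self.n, self.o, self.s, self.p, self.z)

    def isclose(self, other: "ElementalComposition", tol: float = 1e-9) -> bool:
        return all(abs(a - b) <= tol for a, b in zip(self.as_tuple(), other.as_tuple()))

    @property
    def zc(self) -> float:
        return zc(self)


WATER = ElementalComposition(h=2.0, o=1.0)


def zc(comp: ElementalComposition) -> float:
    """Average oxidation state of carbon of ``comp``.

    Raises ``ValueError`` when the composition contains no carbon, for which
    Z_C is undefined.
    """
    if comp.c <= 0:
        raise ValueError("Z_C is undefined for a composition without carbon")
    return (-comp.h + 3.0 * comp.n + 2.0 * comp.o + 2.0 * comp.s) / comp.c


def nosc(comp: ElementalComposition) -> float:
    """Nominal oxidation state of carbon, including P and charge terms.

    NOSC = (z - h + 3n + 2o + 2s - 5p)/c, assigning H +1, N -3, O -2,
    S -2, P +5.  Equals Z_C when p = z = 0; for a nucleotide the phosphate
    and charge terms cancel so NOSC equals the Z_C of the nucleoside.  The
    electron count of a formation reaction from the default basis is
    c * (4 - NOSC).
    """
    if comp.c <= 0:
        raise ValueError("NOSC is undefined for a composition without carbon")
    return (comp.z - comp.h + 3.0 * comp.n + 2.0 * comp.o + 2.0 * comp.s - 5.0 * comp.p) / comp.c


def combine(
    parts: Iterable[Tuple[ElementalComposition, float]],
) -> ElementalComposition:
    """Element-wise weighted sum of compositions.

    With weights normalised to mean 1 this is the average per-monomer
    formula; Z_C of the result is the carbon-weighted mean of the member
    Z_C values.  Raises on empty input or all-zero weights.
    """
    parts = list(parts)
    if not parts:
        raise ValueError("combine() requires at least one (composition, weight) pair")
    total = ElementalComposition()
    weight_sum = 0.0
    for comp, w in parts:
        if w < 0:
            raise ValueError("weights must be >= 0")
        weight_sum += w
        total = total + comp * w
    if weight_sum == 0:
        raise ValueError("combine() requires at least one nonzero weight")
    return total


def average(parts: Sequence[Tuple[ElementalComposition, float]]) -> ElementalComposition:
    """Weighted mean composition (weights normalised to sum 1)."""
    total = combine(parts)
    wsum = sum(w for _, w in parts)
    return total * (1.0 / wsum)


def dehydrate(comp: ElementalComposition, n_water: float = 1.0) -> ElementalComposition:
    """Remove ``n_water`` molecules of H2O, as in polymerisation.

    Dehydration changes the numerator of Z_C by -(-2) + 2*(-1) = 0, so the
    result has exactly the same Z_C as the input.  Raises if the removal
    would drive hydrogen or oxygen negative.
    """
    h = comp.h - 2.0 * n_water
    o = comp.o - 1.0 * n_water
    if h < 0 or o < 0:
        raise ValueError("dehydration would produce negative H or O count")
    return ElementalComposition(comp.c, h, comp.n, o, comp.s, comp.p, comp.z)


def parse_formula(formula: str, charge: float | None = None) -> ElementalComposition:
    """Parse a Hill-order formula string, e.g. ``C2.5H6NO2`` or ``HPO4-2``.

    Subscripts may be fractional.  A trailing ``+``/``-`` with an optional
    integer gives the formal charge; an explicit ``charge`` argument
    overrides it.  An empty formula (the electron) parses to all zeros.
    """
    s = formula.strip()
    z = 0.0
    m = _CHARGE.search(s)
    if m:
        mag = int(m.group(2)) if m.group(2) else 1
        z = mag if m.group(1) == "+" else -mag
        s = s[: m.start()]
    counts = {v: 0.0 for v in _FIELD_BY_SYMBOL.values()}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if not m:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        symbol, sub = m.group(1), m.group(2)
        if symbol not in _FIELD_BY_SYMBOL:
            raise ValueError(f"unsupported element {symbol!r} in formula {formula!r}")
        counts[_FIELD_BY_SYMBOL[symbol]] += float(sub) if sub else 1.0
        pos = m.end()
    if charge is not None:
        z = float(charge)
    return ElementalComposition(z=z, **counts)
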