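"""Elemental composition arithmetic.

``ElementCounts`` is the universal currency of formula and mass
computation: a signed per-element atom tally.  Deltas (e.g. the atoms a
hydroxyl group adds to a chain) may carry negative counts; a physically
realized lipid must end up with all counts >= 0 before a formula string
or a mass is produced.
"""

from __future__ import annotations

from .errors import ConfigurationError, ContractViolation

# IUPAC monoisotopic atomic masses (Da).  Na/K/Cl are present for adduct
# chemistry only and never occur in a neutral lipid skeleton.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.007825032,
    "N": 14.003074,
    "O": 15.994914620,
    "P": 30.973762,
    "S": 31.972071,
    "Na": 22.989769282,
    "K": 38.963706487,
    "Cl": 34.968852682,
}

ELECTRON_MASS = 0.000548580

_HILL_TAIL = sorted(e for e in MONOISOTOPIC_MASS if e not in ("C", "H"))


class ElementCounts(dict):
    """Signed per-element atom tally; behaves like a ``dict[str, int]``.

    Addition/subtraction are element-wise; multiplication by an integer
    scales every count.  Unknown element symbols are rejected eagerly so
    a typo in a registry table fails at load time, not at mass time.
    """

    def __init__(self, counts: dict[str, int] | None = None, **kw: int):
        super().__init__()
        merged = dict(counts or {})
        merged.update(kw)
        for sym, n in merged.items():
            if sym not in MONOISOTOPIC_MASS:
                raise ConfigurationError(f"unknown element symbol: {sym!r}")
            if n:
                self[sym] = int(n)

    def __add__(self, other: "ElementCounts") -> "ElementCounts":
        out = ElementCounts(self)
        for sym, n in other.items():
            out[sym] = out.get(sym, 0) + n
            if out[sym] == 0:
                del out[sym]
        return out

    def __sub__(self, other: "ElementCounts") -> "ElementCounts":
        return self + (other * -1)

    def __mul__(self, k: int) -> "ElementCounts":
        return ElementCounts({sym: n * k for sym, n in self.items()})

    __rmul__ = __mul__

    def copy(self) -> "ElementCounts":
        return ElementCounts(self)


def add_elements(a: ElementCounts, b: ElementCounts) -> ElementCounts:
    """Element-wise sum; inputs are not modified."""
    return ElementCounts(a) + ElementCounts(b)


def formula_string(ec: ElementCounts) -> str:
    """Render a composition in Hill order (C, H, then alphabetical).

    Zero counts are omitted, a count of one is written without a digit.
    Negative counts indicate a delta rather than a molecule and are a
    contract violation here.
    """
    neg = [s for s, n in ec.items() if n < 0]
    if neg:
        raise ContractViolation(f"negative element count for {neg} in formula")
    parts = []
    for sym in ("C", "H", *_HILL_TAIL):
        n = ec.get(sym, 0)
        if n == 0:
            continue
        parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)


def parse_formula(text: str) -> ElementCounts:
    """Inverse of :func:`formula_string` for valid Hill-order strings."""
    import re

    out: dict[str, int] = {}
    pos = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ContractViolation(f"malformed formula {text!r} at offset {pos}")
        pos = m.end()
        out[m.group(1)] = out.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(text):
        raise ContractViolation(f"malformed formula {text!r} at offset {pos}")
    return ElementCounts(out)


def monoisotopic_mass(ec: ElementCounts, charge: int = 0) -> float:
    """Monoisotopic mass in Da; for charged species, m/z.

    The neutral mass is the count-weighted sum of monoisotopic atomic
    masses; each positive charge removes one electron mass (and each
    negative charge adds one).  For ``charge != 0`` the result is divided
    by ``|charge|``.
    """
    neg = [s for s, n in ec.items() if n < 0]
    if neg:
        raise ContractViolation(f"negative element count for {neg} in mass")
    mass = sum(MONOISOTOPIC_MASS[sym] * n for sym, n in ec.items())
    mass -= charge * ELECTRON_MASS
    if charge:
        return mass / abs(charge)
    return mass


WATER = ElementCounts({"H": 2, "O": 1})
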