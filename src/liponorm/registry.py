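"""Data tables: lipid classes, functional groups, adducts.

All three registries are plain data so that extending coverage (a new
class, group or adduct) is an additive table entry, never new code.

Head-group ``element_template`` values are the composition of the class
scaffold *without* any chain: glycerol C3H8O3 for the neutral
glycerolipids, glycerophospho-X for the GP classes, ethanolamine for
NAE, cholesterol for CE.  The chemistry module adds each chain's free
composition and removes one water per ester/ether/amide bond formed, so
e.g. PE 16:0/18:1 = C5H14NO6P + C16H32O2 + C18H34O2 - 2 H2O.

Functional-group ``element_delta`` values are complete atom deltas
(hydrogens included) relative to the undecorated chain; hydroxy is +O
(an H is traded for OH), oxo is +O -2H, carboxy is +C +2O (the added
carbon's two hydrogens are spent on the C=O), methyl is +C +2H.
``dbe_contribution`` is what the group adds to the displayed DBE tally
when a name is aggregated to sn-position level or coarser.
"""

from __future__ import annotations

from .elements import ElementCounts
from .errors import UnsupportedLipid
from .model import Adduct, BondType, Category, FunctionalGroup, Headgroup

E = ElementCounts
_GLYCEROL = {"C": 3, "H": 8, "O": 3}

_ES = BondType.ESTER

HEADGROUPS: dict[str, Headgroup] = {}


def _hg(name: str, cat: Category, template: dict, slots: tuple[BondType, ...]) -> None:
    HEADGROUPS[name] = Headgroup(name, cat, E(template), slots)


# fatty acyls
_hg("FA", Category.FA, {}, (BondType.FREE,))
_hg("NAE", Category.FA, {"C": 2, "H": 7, "N": 1, "O": 1}, (BondType.AMIDE,))
# glycerolipids
_hg("MG", Category.GL, _GLYCEROL, (_ES,))
_hg("DG", Category.GL, _GLYCEROL, (_ES, _ES))
_hg("TG", Category.GL, _GLYCEROL, (_ES, _ES, _ES))
# glycerophospholipids (scaffold = glycerophospho-head)
_hg("PA", Category.GP, {"C": 3, "H": 9, "O": 6, "P": 1}, (_ES, _ES))
_hg("PC", Category.GP, {"C": 8, "H": 20, "N": 1, "O": 6, "P": 1}, (_ES, _ES))
_hg("PE", Category.GP, {"C": 5, "H": 14, "N": 1, "O": 6, "P": 1}, (_ES, _ES))
_hg("PG", Category.GP, {"C": 6, "H": 15, "O": 8, "P": 1}, (_ES, _ES))
_hg("PI", Category.GP, {"C": 9, "H": 19, "O": 11, "P": 1}, (_ES, _ES))
_hg("PS", Category.GP, {"C": 6, "H": 14, "N": 1, "O": 8, "P": 1}, (_ES, _ES))
_hg("LPA", Category.GP, {"C": 3, "H": 9, "O": 6, "P": 1}, (_ES,))
_hg("LPC", Category.GP, {"C": 8, "H": 20, "N": 1, "O": 6, "P": 1}, (_ES,))
_hg("LPE", Category.GP, {"C": 5, "H": 14, "N": 1, "O": 6, "P": 1}, (_ES,))
# sphingolipids (scaffold beyond sphingoid base + N-acyl)
_hg("Cer", Category.SP, {}, (BondType.LCB, BondType.AMIDE))
_hg("SM", Category.SP, {"C": 5, "H": 12, "N": 1, "O": 3, "P": 1},
    (BondType.LCB, BondType.AMIDE))
# sterol esters
_hg("CE", Category.ST, {"C": 27, "H": 46, "O": 1}, (_ES,))


def headgroup(class_name: str) -> Headgroup:
    try:
        return HEADGROUPS[class_name]
    except KeyError:
        raise UnsupportedLipid(f"unknown lipid class {class_name!r}") from None


# name -> (element_delta, dbe_contribution)
FUNCTIONAL_GROUPS: dict[str, tuple[ElementCounts, int]] = {
    "OH": (E({"O": 1}), 0),
    "oxo": (E({"O": 1, "H": -2}), 1),
    "Me": (E({"C": 1, "H": 2}), 0),
    "Et": (E({"C": 2, "H": 4}), 0),
    "Ep": (E({"O": 1, "H": -2}), 1),
    "OOH": (E({"O": 2}), 0),
    "COOH": (E({"C": 1, "O": 2}), 1),
    "NH2": (E({"N": 1, "H": 1}), 0),
    "SH": (E({"S": 1}), 0),
    "OMe": (E({"C": 1, "H": 2, "O": 1}), 0),
}

# Canonical print order of functional-group clauses within a chain.
# Cycles and branches come first, then simple groups in this fixed
# precedence; a registry name missing from the list sorts last,
# alphabetically.
GROUP_PRINT_ORDER: tuple[str, ...] = (
    "Me", "Et", "Ep", "OMe", "OH", "OOH", "NH2", "SH", "oxo", "COOH",
)


def make_group(name: str, position: int = -1, count: int = 1,
               stereo: str = "") -> FunctionalGroup:
    try:
        delta, dbe = FUNCTIONAL_GROUPS[name]
    except KeyError:
        raise UnsupportedLipid(f"unknown functional group {name!r}") from None
    return FunctionalGroup(name=name, position=position, count=count,
                           stereo=stereo, element_delta=delta.copy(),
                           dbe_contribution=dbe)


# adduct token -> (element delta, charge)
ADDUCTS: dict[str, tuple[ElementCounts, int]] = {
    "+H": (E({"H": 1}), +1),
    "+2H": (E({"H": 2}), +2),
    "+3H": (E({"H": 3}), +3),
    "+NH4": (E({"N": 1, "H": 4}), +1),
    "+Na": (E({"Na": 1}), +1),
    "+K": (E({"K": 1}), +1),
    "-H": (E({"H": -1}), -1),
    "-2H": (E({"H": -2}), -2),
    "+Cl": (E({"Cl": 1}), -1),
    "+HCOO": (E({"C": 1, "H": 1, "O": 2}), -1),
    "+CH3COO": (E({"C": 2, "H": 3, "O": 2}), -1),
}


def make_adduct(token: str, charge_count: int, charge_sign: int) -> Adduct:
    """Build an adduct from an '[M+X]n±' clause, validating consistency."""
    try:
        delta, charge = ADDUCTS[token]
    except KeyError:
        raise UnsupportedLipid(f"unknown adduct {token!r}") from None
    if charge_count * charge_sign != charge:
        raise UnsupportedLipid(
            f"adduct {token!r} implies charge {charge:+d}, "
            f"clause says {charge_count * charge_sign:+d}"
        )
    return Adduct(name=token, element_delta=delta.copy(), charge=charge)
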