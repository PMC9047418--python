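"""Systematic IUPAC-IUB fatty acyl names -> structural model.

Translates names like "5-methyl-octadecanoic acid" or
"11R-hydroxy-9,15-dioxo-2,3,4,5-tetranor-prostan-1,20-dioic acid" into
the same Lipid model the shorthand dialects produce, so one printer
yields the standardized shorthand.

Numbering rules adopted:

* substituent and double-bond locants refer to the parent skeleton's
  numbering (prostane numbering for prostane parents), and are mapped
  to the nor-reduced skeleton by renumbering the remaining carbons
  consecutively from the acid carbon;
* "-dioic" names keep the C1 carboxyl inside the chain (as any fatty
  acid does) and express the far carboxyl as a COOH functional group on
  the last remaining chain carbon, so the chain carbon count is one
  less than the skeleton's;
* "epoxy" locant pairs are stored once, at the lower position;
* "(±)" racemic markers parse and are discarded; R/S descriptors are
  kept in the model but the reported level stays at full structure, so
  printed names carry positions and Z/E only.

Triple bonds ("-ynoic") are recognized and rejected as unrepresentable.
"""

from __future__ import annotations

from functools import lru_cache

from ..errors import ContractViolation, UnsupportedLipid
from ..grammar import Grammar, load_builtin
from ..model import (
    BondType,
    Chain,
    Cycle,
    FunctionalGroup,
    Lipid,
    LipidAdduct,
    LipidLevel,
)
from ..parser import ParseTree, parse
from ..registry import headgroup, make_group
from . import _common as c

DIALECT = "IUPAC-FA"

_UNITS = {1: "hen", 2: "do", 3: "tri", 4: "tetra", 5: "penta",
          6: "hexa", 7: "hepta", 8: "octa", 9: "nona"}


def _build_multipliers() -> dict[str, int]:
    """Stem (sans final 'a') -> carbon count, 1..60."""
    lex: dict[str, int] = {
        "meth": 1, "eth": 2, "prop": 3, "but": 4, "pent": 5, "hex": 6,
        "hept": 7, "oct": 8, "non": 9, "dec": 10, "undec": 11, "dodec": 12,
        "icos": 20, "eicos": 20, "henicos": 21, "heneicos": 21,
        "triacont": 30, "tetracont": 40, "pentacont": 50, "hexacont": 60,
    }
    for u in range(3, 10):
        lex[_UNITS[u] + "dec"] = 10 + u
    for u in range(2, 10):
        lex[_UNITS[u] + "cos"] = 20 + u
    for tens, base in ((30, "triacont"), (40, "tetracont"), (50, "pentacont")):
        for u in range(1, 10):
            lex[_UNITS[u] + base] = tens + u
    return lex


MULTIPLIERS = _build_multipliers()
COUNT_PREFIXES = {"di": 2, "tri": 3, "tetra": 4, "penta": 5, "hexa": 6}

# substituent name -> registry group token (None: handled specially)
SUBSTITUENTS = {
    "hydroxy": "OH",
    "oxo": "oxo",
    "hydroperoxy": "OOH",
    "carboxy": "COOH",
    "methoxy": "OMe",
    "amino": "NH2",
    "sulfanyl": "SH",
    "epoxy": None,
    "alkyl": None,
}

PROSTANE_CARBONS = 20
PROSTANE_RING = (8, 12)


@lru_cache(maxsize=1)
def grammar() -> Grammar:
    return load_builtin("iupac_fa.g", DIALECT)


def _locants(node: ParseTree) -> list[tuple[int, str]]:
    out = []
    for loc in node.find_all("locant"):
        num = int(c.direct(loc, "number")[0].matched())
        stereo_nodes = c.direct(loc, "locant_stereo")
        out.append((num, stereo_nodes[0].matched() if stereo_nodes else ""))
    return out


class _NameInfo:
    """Flat record of everything the derivation tree says."""

    def __init__(self) -> None:
        self.subs: list[tuple[str, int, list[tuple[int, str]]]] = []
        self.nor_removed: set[int] = set()
        self.db_locants: list[tuple[int, str]] = []
        self.skeleton: int = 0
        self.ring: tuple[int, int] | None = None
        self.n_db: int = 0
        self.end: str = ""
        self.dioic_locants: list[int] = []


def _read_prefixes(info: _NameInfo, prefix_list: ParseTree) -> None:
    for prefix in prefix_list.find_all("prefix"):
        node = prefix.children[0]
        locs = _locants(c.direct(node, "locants")[0])
        if node.label == "nor_prefix":
            n = COUNT_PREFIXES[c.direct(node, "cmult")[0].matched()]
            if len(locs) != n:
                raise UnsupportedLipid(
                    f"nor prefix removes {n} carbons but names {len(locs)}"
                )
            info.nor_removed.update(p for p, _ in locs)
        elif node.label == "sub_prefix":
            cm = c.direct(node, "cmult_opt")[0].matched()
            count = COUNT_PREFIXES.get(cm, 1)
            sub = c.direct(node, "substname")[0]
            alk = c.direct(sub, "alkyl")
            if alk:
                stem = c.direct(alk[0], "mult")[0].matched()
                info.subs.append(("alkyl", MULTIPLIERS[stem], locs))
            else:
                name = sub.matched()
                expected = 2 * count if name == "epoxy" else count
                if len(locs) != expected:
                    raise UnsupportedLipid(
                        f"{cm or ''}{name} expects {expected} locants, "
                        f"got {len(locs)}"
                    )
                info.subs.append((name, 0, locs))
        else:  # bare locants: double-bond positions
            info.db_locants.extend(locs)


def _read_core(info: _NameInfo, core: ParseTree) -> None:
    node = core.children[0]
    if node.label == "prost_core":
        info.skeleton = PROSTANE_CARBONS
        info.ring = PROSTANE_RING
    else:
        stem = c.direct(node, "mult")[0].matched()
        info.skeleton = MULTIPLIERS[stem]
        if node.label == "unsat_core":
            if c.direct(node, "kind")[0].matched() == "yn":
                raise UnsupportedLipid(
                    "triple bonds cannot be expressed in the shorthand "
                    "nomenclature"
                )
            dblock = c.direct(node, "dblock")[0]
            ncount_node = dblock.find("ncount")
            info.n_db = COUNT_PREFIXES[ncount_node.matched()] if ncount_node else 1
            loc_node = dblock.find("locants")
            if loc_node is not None:
                info.db_locants.extend(_locants(loc_node))
    end = c.direct(node, "acid_end")[0]
    text = end.matched()
    if text == "oyl":
        info.end = "oyl"
    elif "dioic" in text:
        info.end = "dioic"
        loc_node = end.find("locants")
        if loc_node is not None:
            info.dioic_locants = [p for p, _ in _locants(loc_node)]
    else:
        info.end = "oic"


def _build_lipid(info: _NameInfo, class_name: str) -> Lipid:
    if info.nor_removed - set(range(1, info.skeleton + 1)):
        raise UnsupportedLipid("nor locant outside the parent skeleton")
    remaining = [p for p in range(1, info.skeleton + 1)
                 if p not in info.nor_removed]
    renumber = {old: new for new, old in enumerate(remaining, start=1)}
    n_remaining = len(remaining)

    def map_pos(old: int, what: str) -> int:
        if old not in renumber:
            raise UnsupportedLipid(
                f"{what} locant {old} names a removed or absent carbon"
            )
        return renumber[old]

    groups: list[FunctionalGroup] = []
    if info.end == "dioic":
        if info.dioic_locants and sorted(info.dioic_locants) != [
            remaining[0], remaining[-1]
        ]:
            raise UnsupportedLipid(
                "dioic locants must name the two terminal carbons"
            )
        num_carbons = n_remaining - 1
        cooh = make_group("COOH", position=num_carbons)
        groups.append(cooh)
    else:
        num_carbons = n_remaining

    for name, alkyl_carbons, locs in info.subs:
        if name == "alkyl":
            for old, stereo in locs:
                pos = map_pos(old, "alkyl")
                if alkyl_carbons == 1:
                    groups.append(make_group("Me", position=pos, stereo=stereo))
                elif alkyl_carbons == 2:
                    groups.append(make_group("Et", position=pos, stereo=stereo))
                else:
                    groups.append(FunctionalGroup(
                        name="alkyl", position=pos, stereo=stereo,
                        element_delta=c.ALKYL_BRANCH_DELTA.copy(),
                        attachment=Chain(num_carbons=alkyl_carbons,
                                         bond_type=BondType.FREE),
                    ))
        elif name == "epoxy":
            pairs = sorted(map_pos(p, "epoxy") for p, _ in locs)
            for lo, hi in zip(pairs[::2], pairs[1::2]):
                if hi != lo + 1:
                    raise UnsupportedLipid(
                        f"epoxy bridge {lo},{hi} must span adjacent carbons"
                    )
                groups.append(make_group("Ep", position=lo))
        else:
            token = SUBSTITUENTS[name]
            for old, stereo in locs:
                groups.append(make_group(
                    token, position=map_pos(old, name),
                    stereo=stereo if stereo in ("R", "S") else "",
                ))

    chain = Chain(num_carbons=num_carbons, num_dbe=info.n_db,
                  bond_type=BondType.FREE)
    for old, stereo in info.db_locants:
        pos = map_pos(old, "double-bond")
        chain.db_positions[pos] = stereo if stereo in ("Z", "E") else ""
    if len(chain.db_positions) not in (0, info.n_db):
        raise UnsupportedLipid(
            f"{info.n_db} double bonds but {len(chain.db_positions)} locants"
        )

    if info.ring is not None:
        start, end = (map_pos(p, "ring") for p in info.ring)
        cycle = Cycle(start_position=start, end_position=end,
                      cycle_carbons=end - start + 1)
        cycle.internal_groups = [g for g in groups
                                 if start <= g.position <= end
                                 and g.attachment is None]
        chain.functional_groups = [g for g in groups
                                   if g not in cycle.internal_groups]
        chain.cycles = [cycle]
    else:
        chain.functional_groups = groups

    hg = headgroup(class_name)
    chain.bond_type = hg.slot_bonds[0]
    chain.sn_index = 1
    level = min(c.detect_level([chain], []), LipidLevel.FULL_STRUCTURE)
    lipid = Lipid(headgroup=hg, chains=[chain], level=level)
    try:
        lipid.validate()
    except ContractViolation as exc:
        raise UnsupportedLipid(str(exc)) from None
    return lipid


def build(tree: ParseTree, name: str) -> LipidAdduct:
    root = tree.children[0]
    info = _NameInfo()
    _read_prefixes(info, root.find("prefix_list"))
    _read_core(info, root.find("core"))
    if root.label == "nae":
        if info.end != "oyl":
            raise UnsupportedLipid("N-acyl ethanolamine requires an -oyl acyl")
        lipid = _build_lipid(info, "NAE")
    else:
        if info.end == "oyl":
            raise UnsupportedLipid("bare acyl fragment is not a lipid name")
        lipid = _build_lipid(info, "FA")
    return LipidAdduct(lipid=lipid, source_dialect=DIALECT,
                       original_name=name)


def parse_iupac_fa(name: str) -> LipidAdduct:
    """Parse a systematic IUPAC-IUB fatty acyl name."""
    return build(parse(grammar(), name), name)
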