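"""Shared tree-to-model building blocks for the dialect parsers.

All shorthand-style grammars (updated shorthand, LIPID MAPS,
SwissLipids, HMDB, legacy Goslin) share rule names for the structural
core — ``cd``, ``db_block``, ``mods``, ``fg``, ``cycle`` — so one set of
builders serves every dialect; each dialect module supplies only its
grammar file, class-name aliases and surface quirks.
"""

from __future__ import annotations

from ..elements import ElementCounts
from ..errors import ContractViolation, UnsupportedLipid
from ..model import (
    AggregatedInfo,
    BondType,
    Chain,
    Cycle,
    FunctionalGroup,
    Lipid,
    LipidLevel,
)
from ..parser import ParseTree
from ..registry import headgroup, make_adduct, make_group

L = LipidLevel

# complete atom deltas of the two branch kinds, attachment excluded:
# ester-linked acyl branch (-H +O-C(=O)R) and plain alkyl branch (-H +R)
ACYL_BRANCH_DELTA = ElementCounts({"O": 2, "H": -4})
ALKYL_BRANCH_DELTA = ElementCounts({"H": -2})


def direct(node: ParseTree, label: str) -> list[ParseTree]:
    return [c for c in node.children if c.label == label]


def _int(node: ParseTree) -> int:
    return int(node.matched())


def build_core_chain(node: ParseTree, bond: BondType = BondType.ESTER) -> Chain:
    """Build a Chain from a ``core_chain`` (or ``cd``-rooted) node."""
    cd = node if node.label == "cd" else direct(node, "cd")[0]
    nums = direct(cd, "number")
    chain = Chain(num_carbons=_int(nums[0]), num_dbe=_int(nums[1]),
                  bond_type=bond)
    for block in direct(cd, "db_block"):
        for item in block.find_all("db_item"):
            pos = _int(direct(item, "number")[0])
            cfgs = direct(item, "db_config")
            chain.db_positions[pos] = cfgs[0].matched() if cfgs else ""
    mods = direct(node, "mods")
    if mods:
        _apply_mods(chain, mods[0])
    return chain


def _apply_mods(chain: Chain, mods_node: ParseTree) -> None:
    for mod in mods_node.find_all("mod"):
        clause = direct(mod, "clause")[0].children[0]
        if clause.label == "oxy_agg":
            nums = direct(clause, "number")
            chain.agg_oxygens += _int(nums[0]) if nums else 1
        elif clause.label == "cycle":
            chain.cycles.append(_build_cycle(clause))
        else:  # fg_list
            for fg in clause.find_all("fg"):
                chain.functional_groups.append(_build_group(fg.children[0]))


def _build_cycle(node: ParseTree) -> Cycle:
    nums = direct(node, "number")
    cy = Cycle(start_position=_int(nums[0]), end_position=_int(nums[1]),
               cycle_carbons=_int(nums[2]), cycle_dbe=_int(nums[3]))
    if cy.start_position >= cy.end_position:
        raise UnsupportedLipid(
            f"cycle span {cy.start_position}-{cy.end_position} is inverted"
        )
    inner = direct(node, "mods")
    if inner:
        carrier = Chain(num_carbons=0)
        _apply_mods(carrier, inner[0])
        if carrier.agg_oxygens or carrier.cycles:
            raise UnsupportedLipid("unsupported clause inside a cycle")
        cy.internal_groups = carrier.functional_groups
    return cy


def _build_group(node: ParseTree) -> FunctionalGroup:
    kind = node.label
    nums = direct(node, "number")
    if kind == "acyl_branch":
        attachment = build_core_chain(direct(node, "core_chain")[0])
        return FunctionalGroup(
            name="O", position=_int(nums[0]) if nums else -1,
            element_delta=ACYL_BRANCH_DELTA.copy(), dbe_contribution=1,
            attachment=attachment,
        )
    if kind == "alkyl_branch":
        attachment = build_core_chain(direct(node, "core_chain")[0],
                                      bond=BondType.FREE)
        return FunctionalGroup(
            name="alkyl", position=_int(nums[0]) if nums else -1,
            element_delta=ALKYL_BRANCH_DELTA.copy(), dbe_contribution=0,
            attachment=attachment,
        )
    name_node = direct(node, "fg_name")[0]
    name = name_node.matched()
    if kind == "pos_fg":
        stereo_nodes = direct(node, "stereo_br")
        stereo = stereo_nodes[0].matched()[1:-1] if stereo_nodes else ""
        return make_group(name, position=_int(nums[0]), stereo=stereo)
    if kind == "counted_fg":
        return make_group(name, count=_int(nums[0]))
    return make_group(name)


def _iter_full_groups(chain: Chain):
    yield from chain.functional_groups
    for cy in chain.cycles:
        yield from cy.internal_groups


def detect_level(chains: list[Chain], separators: list[str]) -> LipidLevel:
    """Finest level the structural information of a parsed name supports."""
    if "_" in separators:
        return L.MOLECULAR_SPECIES
    if any(ch.agg_oxygens for ch in chains):
        return L.SN_POSITION
    sd_trigger = False
    full_ok = True
    stereo_present = False

    def scan(ch: Chain) -> None:
        nonlocal sd_trigger, full_ok, stereo_present
        if ch.db_positions or ch.cycles:
            sd_trigger = True
        if len(ch.db_positions) < ch.num_dbe:
            full_ok = False
        if any(cfg == "" for cfg in ch.db_positions.values()):
            full_ok = False
        for g in _iter_full_groups(ch):
            sd_trigger = True
            if g.position == -1 or g.count > 1:
                full_ok = False
            if g.stereo:
                stereo_present = True
            if g.attachment is not None:
                scan(g.attachment)

    for ch in chains:
        if not ch.is_empty:
            scan(ch)
    if not sd_trigger:
        return L.SN_POSITION
    if not full_ok:
        return L.STRUCTURE_DEFINED
    return L.COMPLETE_STRUCTURE if stereo_present else L.FULL_STRUCTURE


def assemble_lipid(class_name: str, chains: list[Chain],
                   separators: list[str]) -> Lipid:
    """Combine a class token and parsed chains into a leveled Lipid."""
    hg = headgroup(class_name)
    aggregated = not separators and len(chains) == 1 and hg.max_chains > 1
    if aggregated:
        ch = chains[0]
        if ch.db_positions or ch.functional_groups or ch.cycles:
            raise UnsupportedLipid(
                "species-level totals cannot carry positional information"
            )
        bonds = list(hg.slot_bonds)
        if ch.bond_type in (BondType.ETHER_PLASMANYL,
                            BondType.ETHER_PLASMENYL):
            bonds[0] = ch.bond_type
        lipid = Lipid(
            headgroup=hg,
            level=L.SPECIES,
            aggregated_info=AggregatedInfo(ch.num_carbons, ch.num_dbe,
                                           ch.agg_oxygens),
            species_bonds=tuple(bonds),
        )
        return lipid
    sn_known = "_" not in separators
    for i, ch in enumerate(chains):
        slot_bond = hg.slot_bonds[i] if i < len(hg.slot_bonds) else BondType.ESTER
        if ch.bond_type not in (BondType.ETHER_PLASMANYL,
                                BondType.ETHER_PLASMENYL):
            ch.bond_type = slot_bond
        ch.sn_index = i + 1 if sn_known else -1
    detected = detect_level(chains, separators)
    lipid = Lipid(headgroup=hg, chains=chains,
                  level=L.COMPLETE_STRUCTURE)
    try:
        lipid.validate()
    except ContractViolation as exc:
        raise UnsupportedLipid(str(exc)) from None
    # canonicalize: a name whose information only supports level X must
    # not keep finer-grained fragments (e.g. positioned groups next to
    # an aggregated ';O2' chain) — fold down to the detected level
    from ..normalize import aggregate_to_level

    return aggregate_to_level(lipid, detected)


def build_adduct(node: ParseTree):
    """Adduct from an ``adduct_clause`` node, validated against the registry."""
    token = direct(node, "adduct_token")[0].matched()
    count = _int(direct(node, "number")[0])
    sign = 1 if direct(node, "adduct_sign")[0].matched() == "+" else -1
    return make_adduct(token, count, sign)
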