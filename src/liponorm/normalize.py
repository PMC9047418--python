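"""Hierarchy-level aggregation and canonical name printing.

A parsed lipid sits at the finest level its name encodes; this module
lifts it to any coarser level by discarding information in the defined
order (stereo -> positions/configurations -> functional-group identity
-> sn assignment -> per-chain identity -> class -> category) and renders
the canonical shorthand string for the level reached.

Functional-group clauses print in a fixed precedence: carbocycles
first, then acyl/alkyl branches by position, then simple groups in the
registry's canonical order (Me, Et, Ep, OMe, OH, OOH, NH2, SH, oxo,
COOH; unknown names last, alphabetically).  Within one clause, entries
are ordered by ascending position.
"""

from __future__ import annotations

import copy

from .errors import LevelError
from .model import (
    AggregatedInfo,
    BondType,
    Chain,
    Cycle,
    FunctionalGroup,
    Lipid,
    LipidLevel,
)
from .registry import GROUP_PRINT_ORDER

L = LipidLevel


def _walk_groups(chain: Chain):
    """Yield every functional group of a chain, nested ones included."""
    stack = list(chain.functional_groups)
    for cy in chain.cycles:
        stack.extend(cy.internal_groups)
    while stack:
        g = stack.pop()
        yield g
        if g.attachment is not None:
            stack.extend(g.attachment.functional_groups)
            for cy in g.attachment.cycles:
                stack.extend(cy.internal_groups)


def aggregate_to_level(lipid: Lipid, target: LipidLevel) -> Lipid:
    """Return a copy of ``lipid`` reduced to the coarser ``target`` level.

    Raises :class:`LevelError` if ``target`` is finer than what the
    lipid knows — information can be discarded, never invented.
    """
    if target > lipid.level:
        raise LevelError(
            f"cannot refine {lipid.level.name} lipid to {target.name}"
        )
    out = copy.deepcopy(lipid)
    if target == lipid.level:
        return out
    steps = [
        (L.FULL_STRUCTURE, _drop_stereo),
        (L.STRUCTURE_DEFINED, _drop_positions),
        (L.SN_POSITION, _fold_groups),
        (L.MOLECULAR_SPECIES, _forget_sn),
        (L.SPECIES, _sum_chains),
        (L.CLASS, _drop_chains),
        (L.CATEGORY, _drop_chains),
    ]
    for lvl, transform in steps:
        if lipid.level > lvl >= target:
            transform(out)
            out.level = lvl
    out.level = target
    return out


def _drop_stereo(lipid: Lipid) -> None:
    for ch in lipid.chains:
        for g in _walk_groups(ch):
            g.stereo = ""


def _drop_positions(lipid: Lipid) -> None:
    for ch in lipid.chains:
        ch.db_positions = {pos: "" for pos in ch.db_positions}
        merged: dict[str, FunctionalGroup] = {}
        simple: list[FunctionalGroup] = []
        for g in ch.functional_groups:
            g.position = -1
            if g.attachment is not None:
                simple.append(g)
            elif g.name in merged:
                merged[g.name].count += g.count
            else:
                merged[g.name] = g
        ch.functional_groups = simple + list(merged.values())
        for cy in ch.cycles:
            for g in cy.internal_groups:
                g.position = -1


def _fold_groups(lipid: Lipid) -> None:
    """sn-position level and coarser: functional groups collapse into
    the chain's displayed DBE and a trailing oxygen tally."""
    for ch in lipid.chains:
        if ch.is_empty:
            continue
        plasmenyl = 1 if ch.bond_type is BondType.ETHER_PLASMENYL else 0
        carbons = ch.total_carbons()
        dbe = ch.display_dbe() - plasmenyl
        oxygens = ch.oxygen_tally()
        ch.num_carbons = carbons
        ch.num_dbe = dbe
        ch.agg_oxygens = oxygens
        ch.functional_groups = []
        ch.cycles = []
        ch.db_positions = {}


def _chain_sort_key(ch: Chain):
    return (ch.num_carbons, ch.num_dbe, ch.agg_oxygens,
            ch.bond_type.value)


def _forget_sn(lipid: Lipid) -> None:
    for ch in lipid.chains:
        ch.sn_index = -1
    lipid.chains.sort(key=_chain_sort_key)


def _sum_chains(lipid: Lipid) -> None:
    occupied = [ch for ch in lipid.chains if not ch.is_empty]
    if lipid.aggregated_info is None:
        lipid.aggregated_info = AggregatedInfo(
            total_carbons=sum(ch.num_carbons for ch in occupied),
            total_dbe=sum(
                ch.num_dbe for ch in occupied
            ),
            total_oxygens=sum(ch.agg_oxygens for ch in occupied),
        )
        lipid.species_bonds = tuple(ch.bond_type for ch in occupied)
    lipid.chains = []


def _drop_chains(lipid: Lipid) -> None:
    lipid.chains = []
    lipid.aggregated_info = None


# ---------------------------------------------------------------- printing

def _ox_suffix(n: int) -> str:
    if n <= 0:
        return ""
    return ";O" if n == 1 else f";O{n}"


def _ether_prefix(bond: BondType) -> str:
    if bond is BondType.ETHER_PLASMANYL:
        return "O-"
    if bond is BondType.ETHER_PLASMENYL:
        return "P-"
    return ""


def _db_block(ch: Chain, level: LipidLevel) -> str:
    if not ch.db_positions:
        return ""
    items = []
    for pos in sorted(ch.db_positions):
        cfg = ch.db_positions[pos] if level >= L.FULL_STRUCTURE else ""
        items.append(f"{pos}{cfg}")
    return "(" + ",".join(items) + ")"


def _group_rank(name: str) -> tuple:
    try:
        return (0, GROUP_PRINT_ORDER.index(name))
    except ValueError:
        return (1, name)


def _render_attachment(g: FunctionalGroup, level: LipidLevel) -> str:
    inner = _render_chain_core(g.attachment, level)
    pos = f"{g.position}" if g.position != -1 and level >= L.FULL_STRUCTURE else ""
    if g.name == "O":          # ester-linked acyl branch
        return f"{pos}O(FA {inner})"
    return f"{pos}({inner})"   # alkyl branch


def _render_cycle(cy: Cycle, level: LipidLevel) -> str:
    body = f"{cy.start_position}-{cy.end_position}cy{cy.cycle_carbons}:{cy.cycle_dbe}"
    groups = _render_simple_groups(cy.internal_groups, level)
    return "[" + ";".join([body] + groups) + "]"


def _render_simple_groups(groups: list[FunctionalGroup],
                          level: LipidLevel) -> list[str]:
    """Clause strings for plain (non-branch) groups, canonical order."""
    by_name: dict[str, list[FunctionalGroup]] = {}
    for g in groups:
        by_name.setdefault(g.name, []).append(g)
    clauses = []
    for name in sorted(by_name, key=_group_rank):
        entries = sorted(by_name[name], key=lambda g: g.position)
        if level >= L.FULL_STRUCTURE:
            parts = []
            for g in entries:
                stereo = f"[{g.stereo}]" if g.stereo and level >= L.COMPLETE_STRUCTURE else ""
                pos = f"{g.position}" if g.position != -1 else ""
                parts.extend([f"{pos}{name}{stereo}"] * g.count)
            clauses.append(",".join(parts))
        else:
            n = sum(g.count for g in entries)
            clauses.append(name if n == 1 else f"({name}){n}")
    return clauses


def _render_chain_core(ch: Chain, level: LipidLevel) -> str:
    out = f"{ch.num_carbons}:{ch.num_dbe}"
    out += _db_block(ch, level)
    if level >= L.STRUCTURE_DEFINED:
        clauses: list[str] = []
        clauses.extend(_render_cycle(cy, level) for cy in ch.cycles)
        branches = [g for g in ch.functional_groups if g.attachment is not None]
        branches.sort(key=lambda g: g.position)
        clauses.extend(_render_attachment(g, level) for g in branches)
        simple = [g for g in ch.functional_groups if g.attachment is None]
        clauses.extend(_render_simple_groups(simple, level))
        for clause in clauses:
            out += f";{clause}"
    out += _ox_suffix(ch.agg_oxygens)
    return out


def _render_chain(ch: Chain, level: LipidLevel) -> str:
    if ch.is_empty:
        return "0:0"
    return _ether_prefix(ch.bond_type) + _render_chain_core(ch, level)


def print_name(lipid: Lipid, level: LipidLevel | None = None) -> str:
    """Canonical shorthand name of ``lipid`` at ``level`` (default: its
    own level)."""
    level = lipid.level if level is None else level
    lp = aggregate_to_level(lipid, level)
    hg = lp.headgroup
    if level == L.CATEGORY:
        return hg.category.value
    if level == L.CLASS:
        return hg.class_name
    if level == L.SPECIES:
        agg = lp.aggregated_info
        if agg is None:
            return hg.class_name
        bonds = lp.species_bonds or hg.slot_bonds
        prefix = ""
        for b in bonds:
            prefix = _ether_prefix(b) or prefix
        return (f"{hg.class_name} {prefix}{agg.total_carbons}:{agg.total_dbe}"
                + _ox_suffix(agg.total_oxygens))
    sep = "_" if level == L.MOLECULAR_SPECIES else "/"
    chains = lp.chains
    body = sep.join(_render_chain(ch, level) for ch in chains)
    return f"{hg.class_name} {body}"
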