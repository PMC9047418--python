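"""Legacy dialects: LIPID MAPS, SwissLipids, HMDB, original Goslin.

All four share the structural core of the shorthand grammar; what
differs is surface syntax (parenthesized vs space-separated chain
lists, '-' separators, d/t/m sphingoid hydroxylation prefixes, 'e'/'a'/
'p' ether markers) and some class spellings.  Hydroxyl shorthand like
``d18:1`` or ``;2`` is translated into the aggregated-oxygen
representation, which caps the detected level at sn-position — the
positions are genuinely unknown.
"""

from __future__ import annotations

from functools import lru_cache

from ..grammar import Grammar, load_builtin
from ..model import BondType, Chain, LipidAdduct
from ..parser import ParseTree, parse
from . import _common as c

_LCB_OXYGENS = {"m": 1, "d": 2, "t": 3}

# dialect -> (grammar file, class-name aliases)
_DIALECTS: dict[str, tuple[str, dict[str, str]]] = {
    "LIPIDMAPS": ("lipidmaps.g", {}),
    "SWISSLIPIDS": ("swisslipids.g", {}),
    "HMDB": ("hmdb.g", {"LysoPC": "LPC", "LysoPE": "LPE", "LysoPA": "LPA"}),
    "GOSLIN": ("goslin.g", {"TAG": "TG", "DAG": "DG", "MAG": "MG",
                            "ChE": "CE"}),
}


@lru_cache(maxsize=None)
def grammar(dialect: str) -> Grammar:
    return load_builtin(_DIALECTS[dialect][0], dialect)


def _build_chain(node: ParseTree) -> Chain:
    cd = node.find("cd")
    chain = c.build_core_chain(cd)
    lcb = c.direct(node, "lcb_prefix")
    if lcb:
        chain.agg_oxygens += _LCB_OXYGENS[lcb[0].matched()]
    hydroxyl = node.find("hydroxyl")
    if hydroxyl is not None and hydroxyl.children:
        chain.agg_oxygens += int(c.direct(hydroxyl, "number")[0].matched())
    prefix = c.direct(node, "ether_prefix")
    suffix = c.direct(node, "ether_suffix")
    marker = ""
    if prefix:
        marker = prefix[0].matched()[0].lower()
    elif suffix:
        marker = {"e": "o", "a": "o", "p": "p"}[suffix[0].matched()]
    if marker == "o":
        chain.bond_type = BondType.ETHER_PLASMANYL
    elif marker == "p":
        chain.bond_type = BondType.ETHER_PLASMENYL
    return chain


def build(tree: ParseTree, name: str, dialect: str) -> LipidAdduct:
    aliases = _DIALECTS[dialect][1]
    class_name = tree.find("class").matched()
    class_name = aliases.get(class_name, class_name)
    chain_list = tree.find("chain_list")
    if chain_list is None:
        from ..model import Lipid, LipidLevel
        from ..registry import headgroup

        lipid = Lipid(headgroup=headgroup(class_name),
                      level=LipidLevel.CLASS)
        return LipidAdduct(lipid=lipid, source_dialect=dialect,
                           original_name=name)
    chains = [_build_chain(n) for n in chain_list.find_all("chain")]
    # '-' joins chains of unknown sn position, like '_'
    separators = ["_" if n.matched() == "-" else n.matched()
                  for n in chain_list.find_all("sep")]
    lipid = c.assemble_lipid(class_name, chains, separators)
    return LipidAdduct(lipid=lipid, source_dialect=dialect,
                       original_name=name)


def parse_legacy(name: str, dialect: str) -> LipidAdduct:
    """Parse ``name`` under one of the legacy dialect grammars."""
    return build(parse(grammar(dialect), name), name, dialect)
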