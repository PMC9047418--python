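"""Parser for the updated (2020) shorthand nomenclature."""

from __future__ import annotations

from functools import lru_cache

from ..grammar import Grammar, load_builtin
from ..model import BondType, Lipid, LipidAdduct, LipidLevel
from ..parser import ParseTree, parse
from ..registry import headgroup
from . import _common as c

DIALECT = "SHORTHAND2020"


@lru_cache(maxsize=1)
def grammar() -> Grammar:
    return load_builtin("shorthand2020.g", DIALECT)


def _build_chain(chain_node: ParseTree):
    core = c.direct(chain_node, "core_chain")[0]
    chain = c.build_core_chain(core)
    prefixes = c.direct(chain_node, "ether_prefix")
    if prefixes:
        chain.bond_type = (BondType.ETHER_PLASMANYL
                           if prefixes[0].matched() == "O-"
                           else BondType.ETHER_PLASMENYL)
    return chain


def build(tree: ParseTree, name: str) -> LipidAdduct:
    body = tree.find("body")
    class_name = body.find("class").matched()
    chain_list = body.find("chain_list")
    if chain_list is None:
        lipid = Lipid(headgroup=headgroup(class_name), level=LipidLevel.CLASS)
        return LipidAdduct(lipid=lipid, source_dialect=DIALECT,
                           original_name=name)
    chains = [_build_chain(n) for n in chain_list.find_all("chain")]
    separators = [n.matched() for n in chain_list.find_all("sep")]
    lipid = c.assemble_lipid(class_name, chains, separators)
    adduct_node = tree.find("adduct_clause")
    adduct = c.build_adduct(adduct_node) if adduct_node is not None else None
    return LipidAdduct(lipid=lipid, adduct=adduct, source_dialect=DIALECT,
                       original_name=name)


def parse_shorthand(name: str) -> LipidAdduct:
    """Parse a name in the updated shorthand nomenclature.

    The returned lipid carries the finest hierarchy level the string's
    information supports (separators, group names, positions and stereo
    tokens each grant one step).
    """
    return build(parse(grammar(), name), name)
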