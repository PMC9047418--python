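"""liponorm: grammar-based parsing and normalization of lipid names.

Recognizes lipid names in several nomenclature dialects (the updated
shorthand nomenclature, LIPID MAPS, SwissLipids, HMDB, the legacy
Goslin dialect and systematic IUPAC-IUB fatty acyl names), represents
them in a common hierarchical structural model, prints standardized
shorthand at any hierarchy level, and computes elemental sum formulas
and monoisotopic (adduct) masses.

Typical use::

    >>> import liponorm
    >>> la = liponorm.parse_name("PE 16:1(6Z)/16:0;5OH[R],8OH[S];3oxo")
    >>> liponorm.print_name(la.lipid, liponorm.LipidLevel.SPECIES)
    'PE 32:2;O3'
    >>> liponorm.formula_of(la)
    'C37H70NO11P'
"""

from __future__ import annotations

from .chemistry import formula_of, lipid_elements, sum_formula
from .dialects import DIALECT_PRIORITY, parse_any, parse_dialect
from .dialects.iupac import parse_iupac_fa
from .dialects.shorthand import parse_shorthand
from .elements import (
    ElementCounts,
    add_elements,
    formula_string,
    monoisotopic_mass,
    parse_formula,
)
from .errors import (
    GrammarLoadError,
    LevelError,
    LiponormError,
    NotParseable,
    ParseFailure,
    UnsupportedLipid,
)
from .generate import generate_fixture_names
from .grammar import Grammar, load_builtin, load_grammar
from .model import (
    Adduct,
    BondType,
    Category,
    Chain,
    Cycle,
    FunctionalGroup,
    Headgroup,
    Lipid,
    LipidAdduct,
    LipidLevel,
)
from .normalize import aggregate_to_level, print_name
from .parser import ParseTree, parse, visit

__version__ = "0.1.0"

__all__ = [
    "Adduct", "BondType", "Category", "Chain", "Cycle", "DIALECT_PRIORITY",
    "ElementCounts", "FunctionalGroup", "Grammar", "GrammarLoadError",
    "Headgroup", "LevelError", "Lipid", "LipidAdduct", "LipidLevel",
    "LiponormError", "NotParseable", "ParseFailure", "ParseTree",
    "UnsupportedLipid", "add_elements", "aggregate_to_level", "formula_of",
    "formula_string", "generate_fixture_names", "lipid_elements",
    "load_builtin", "load_grammar", "monoisotopic_mass", "normalize_name",
    "parse", "parse_any", "parse_dialect", "parse_formula", "parse_iupac_fa",
    "parse_name", "parse_shorthand", "print_name", "sum_formula", "visit",
]


def parse_name(name: str, dialect: str = "auto") -> LipidAdduct:
    """Parse a lipid name, auto-detecting the dialect by default."""
    if dialect == "auto":
        return parse_any(name)
    return parse_dialect(name, dialect)


def normalize_name(name: str, level: LipidLevel | None = None,
                   dialect: str = "auto") -> str:
    """Parse ``name`` and print the standardized shorthand at ``level``
    (default: the finest level the name supports)."""
    la = parse_name(name, dialect)
    return print_name(la.lipid, level)
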