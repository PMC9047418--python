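"""Dialect registry and dispatch.

``parse_dialect`` parses under one named grammar; ``parse_any`` tries
all dialects in a fixed priority order (most modern and most specific
first, so legacy grammars never shadow updated-nomenclature names) and
returns the first success.
"""

from __future__ import annotations

from ..errors import NotParseable, ParseFailure, UnsupportedLipid
from ..model import LipidAdduct
from .iupac import parse_iupac_fa
from .legacy import parse_legacy
from .shorthand import parse_shorthand

DIALECT_PRIORITY: tuple[str, ...] = (
    "SHORTHAND2020", "LIPIDMAPS", "SWISSLIPIDS", "HMDB", "GOSLIN", "IUPAC-FA",
)


def parse_dialect(name: str, dialect: str) -> LipidAdduct:
    """Parse ``name`` under the given dialect grammar."""
    dialect = dialect.upper().replace("_", "-")
    if dialect == "SHORTHAND2020":
        return parse_shorthand(name)
    if dialect == "IUPAC-FA":
        return parse_iupac_fa(name)
    if dialect in ("LIPIDMAPS", "SWISSLIPIDS", "HMDB", "GOSLIN"):
        return parse_legacy(name, dialect)
    from ..errors import ConfigurationError

    raise ConfigurationError(
        f"unknown dialect {dialect!r}; choose from {DIALECT_PRIORITY}"
    )


def parse_any(name: str) -> LipidAdduct:
    """Try every dialect in priority order; first success wins.

    A grammar match whose chemistry is unrepresentable
    (:class:`UnsupportedLipid`) does not stop the search — another
    dialect may still read the name; if nothing succeeds the first such
    semantic error is re-raised as the most informative one, otherwise
    :class:`NotParseable` reports the furthest failure offset per
    dialect.
    """
    failures: dict[str, int] = {}
    semantic: UnsupportedLipid | None = None
    for dialect in DIALECT_PRIORITY:
        try:
            return parse_dialect(name, dialect)
        except ParseFailure as exc:
            failures[dialect] = exc.offset
        except UnsupportedLipid as exc:
            failures[dialect] = -1
            semantic = semantic or exc
    if semantic is not None:
        raise semantic
    raise NotParseable(name, failures)
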