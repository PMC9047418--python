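"""Memoized backtracking parser over loaded grammars.

The engine enumerates, per (nonterminal, offset), every reachable end
offset, keeping for each end the first derivation in rule order — so a
grammar that is ambiguous for some string still yields exactly one tree,
deterministically (first-listed alternative wins).  Full backtracking
across rule boundaries means a nonterminal's match length is chosen to
make the *whole* input parse, which plain PEG ordered choice cannot
guarantee; this is what lets the nested chain-specification patterns of
the shorthand nomenclature (branches within functional groups within
chains) parse without grammar contortions.

The furthest offset at which any terminal failed to match is tracked for
error reporting, together with the terminals expected there.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from typing import Any, Callable

from .errors import ParseFailure
from .grammar import CharClass, Grammar, Lit, Ref


@dataclass
class ParseTree:
    """Derivation-tree node.

    Rule nodes carry the rule name as ``label``; terminal leaves have
    ``label None`` and hold the matched text.  Concatenating leaf spans
    in order reconstructs the input exactly.
    """

    label: str | None
    start: int
    end: int
    children: list["ParseTree"] = field(default_factory=list)
    text: str = ""

    @property
    def is_leaf(self) -> bool:
        return self.label is None

    def matched(self) -> str:
        """Text covered by this node (concatenation of its leaves)."""
        if self.is_leaf:
            return self.text
        return "".join(c.matched() for c in self.children)

    def leaves(self) -> list["ParseTree"]:
        if self.is_leaf:
            return [self]
        out: list[ParseTree] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def find_all(self, label: str) -> list["ParseTree"]:
        """All descendant rule nodes with the given label (pre-order),
        not descending into a match once found."""
        out: list[ParseTree] = []
        for c in self.children:
            if c.label == label:
                out.append(c)
            else:
                out.extend(c.find_all(label))
        return out

    def find(self, label: str) -> "ParseTree | None":
        hits = self.find_all(label)
        return hits[0] if hits else None

    def depth(self) -> int:
        if not self.children:
            return 1
        return 1 + max(c.depth() for c in self.children)


class _Session:
    """One parse attempt: memo tables and furthest-failure tracking."""

    def __init__(self, grammar: Grammar, text: str):
        self.g = grammar
        self.text = text
        self.memo: dict[tuple[str, int], list[tuple[int, ParseTree]]] = {}
        self.active: set[tuple[str, int]] = set()
        self.far = 0
        self.expected: set[str] = set()

    def _fail_at(self, pos: int, what: str) -> None:
        if pos > self.far:
            self.far = pos
            self.expected = {what}
        elif pos == self.far:
            self.expected.add(what)

    def match_symbol(self, sym, pos: int) -> list[tuple[int, list[ParseTree]]]:
        if isinstance(sym, Lit):
            if not sym.text:
                return [(pos, [])]
            if self.text.startswith(sym.text, pos):
                end = pos + len(sym.text)
                return [(end, [ParseTree(None, pos, end, text=sym.text)])]
            self._fail_at(pos, repr(sym.text))
            return []
        if isinstance(sym, CharClass):
            if pos < len(self.text) and sym.matches(self.text[pos]):
                return [(pos + 1, [ParseTree(None, pos, pos + 1,
                                             text=self.text[pos])])]
            self._fail_at(pos, f"[{sym.source}]")
            return []
        assert isinstance(sym, Ref)
        results = self.parse_rule(sym.name, pos)
        if sym.name in self.g.internal:
            # splice internal (desugared) nodes into the parent
            return [(end, list(tree.children)) for end, tree in results]
        return [(end, [tree]) for end, tree in results]

    def match_sequence(self, symbols, pos: int) -> list[tuple[int, list[ParseTree]]]:
        states: list[tuple[int, list[ParseTree]]] = [(pos, [])]
        for sym in symbols:
            nxt: list[tuple[int, list[ParseTree]]] = []
            seen: set[int] = set()
            for end, trees in states:
                for end2, trees2 in self.match_symbol(sym, end):
                    if end2 not in seen:
                        seen.add(end2)
                        nxt.append((end2, trees + trees2))
            if not nxt:
                return []
            states = nxt
        return states

    def parse_rule(self, rule: str, pos: int) -> list[tuple[int, ParseTree]]:
        key = (rule, pos)
        if key in self.memo:
            return self.memo[key]
        if key in self.active:
            # left-recursive re-entry at the same offset: curtail
            return []
        self.active.add(key)
        results: list[tuple[int, ParseTree]] = []
        seen: set[int] = set()
        for alt in self.g.rules[rule]:
            for end, trees in self.match_sequence(alt, pos):
                if end not in seen:
                    seen.add(end)
                    results.append((end, ParseTree(rule, pos, end, trees)))
        self.active.discard(key)
        self.memo[key] = results
        return results


def parse(grammar: Grammar, text: str) -> ParseTree:
    """Parse ``text`` into a derivation tree covering all of it.

    Input is normalized to NFC first.  Raises :class:`ParseFailure` with
    the furthest failure offset when no derivation covers the input.
    """
    text = unicodedata.normalize("NFC", text)
    session = _Session(grammar, text)
    results = session.parse_rule(grammar.start_symbol, 0)
    for end, tree in results:
        if end == len(text):
            return tree
    offset = session.far
    if results:
        # some prefix parsed; the failure is at the longest such prefix
        offset = max([offset] + [end for end, _ in results])
    raise ParseFailure(text, offset, tuple(session.expected))


Handler = Callable[[ParseTree, Any], Any]


def visit(tree: ParseTree,
          handlers: dict[str, Handler | tuple[Handler | None, Handler | None]],
          state: Any = None) -> Any:
    """Depth-first traversal firing per-rule enter/exit callbacks.

    ``handlers`` maps a rule name to either a single post-order callback
    or an ``(enter, exit)`` pair; callbacks receive ``(node, state)``.
    The (possibly replaced) state is returned.
    """

    def walk(node: ParseTree, state: Any) -> Any:
        pre = post = None
        if node.label is not None and node.label in handlers:
            h = handlers[node.label]
            if isinstance(h, tuple):
                pre, post = h
            else:
                post = h
        if pre is not None:
            out = pre(node, state)
            state = out if out is not None else state
        for child in node.children:
            state = walk(child, state)
        if post is not None:
            out = post(node, state)
            state = out if out is not None else state
        return state

    return walk(tree, state)
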