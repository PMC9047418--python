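"""EBNF-like grammar definition language and loader.

Format, one rule per ``;``-terminated statement::

    # comment (also //)
    rule_name = alternative_1 | alternative_2 | '';

Right-hand sides are sequences of: single- or double-quoted literals
(``''`` matches the empty string), character classes ``[a-z0-9]``,
references to other rules, parenthesized groups, and postfix ``?``,
``*``, ``+``.  Whitespace inside a literal is significant; whitespace
between symbols only separates them.

Repetition and option are desugared at load time into fresh internal
right-recursive rules (marked so the parser splices their tree nodes
away), which keeps the runtime core to plain alternation/sequencing and
makes ``*``/``+`` greedy-by-preference under the first-alternative-wins
determinism policy.  Direct left recursion is rejected at load time;
grammars are authored right-recursively.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field

from .errors import GrammarLoadError


@dataclass(frozen=True)
class Lit:
    text: str


@dataclass(frozen=True)
class CharClass:
    ranges: tuple[tuple[str, str], ...]  # inclusive (lo, hi) pairs
    source: str

    def matches(self, ch: str) -> bool:
        return any(lo <= ch <= hi for lo, hi in self.ranges)


@dataclass(frozen=True)
class Ref:
    name: str


Symbol = Lit | CharClass | Ref
Alternative = tuple[Symbol, ...]


@dataclass
class Grammar:
    """A validated context-free rule set."""

    name: str
    start_symbol: str
    rules: dict[str, list[Alternative]] = field(default_factory=dict)
    internal: set[str] = field(default_factory=set)

    @property
    def nonterminals(self) -> set[str]:
        return set(self.rules)


class _Tok:
    """Tokenizer over the grammar text, tracking line numbers."""

    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.line = 1

    def _skip(self) -> None:
        t, n = self.text, len(self.text)
        while self.pos < n:
            ch = t[self.pos]
            if ch == "\n":
                self.line += 1
                self.pos += 1
            elif ch.isspace():
                self.pos += 1
            elif ch == "#" or t.startswith("//", self.pos):
                while self.pos < n and t[self.pos] != "\n":
                    self.pos += 1
            else:
                break

    def peek(self) -> str:
        self._skip()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def next_token(self) -> tuple[str, str]:
        """Return (kind, value); kinds: ident, lit, class, punct, eof."""
        self._skip()
        t, n = self.text, len(self.text)
        if self.pos >= n:
            return "eof", ""
        ch = t[self.pos]
        if ch in "'\"":
            quote, out, i = ch, [], self.pos + 1
            while i < n and t[i] != quote:
                if t[i] == "\\" and i + 1 < n:
                    out.append(t[i + 1])
                    i += 2
                else:
                    if t[i] == "\n":
                        self.line += 1
                    out.append(t[i])
                    i += 1
            if i >= n:
                raise GrammarLoadError("unterminated literal", self.line)
            self.pos = i + 1
            return "lit", "".join(out)
        if ch == "[":
            i = self.pos + 1
            out = []
            while i < n and t[i] != "]":
                if t[i] == "\\" and i + 1 < n:
                    out.append(t[i:i + 2])
                    i += 2
                else:
                    out.append(t[i])
                    i += 1
            if i >= n:
                raise GrammarLoadError("unterminated character class", self.line)
            self.pos = i + 1
            return "class", "".join(out)
        if ch.isalpha() or ch == "_":
            i = self.pos
            while i < n and (t[i].isalnum() or t[i] == "_"):
                i += 1
            val = t[self.pos:i]
            self.pos = i
            return "ident", val
        self.pos += 1
        return "punct", ch


def _parse_class(src: str, line: int) -> CharClass:
    ranges: list[tuple[str, str]] = []
    i, n = 0, len(src)
    while i < n:
        ch = src[i]
        if ch == "\\" and i + 1 < n:
            ch = src[i + 1]
            i += 2
        else:
            i += 1
        if i + 1 < n and src[i] == "-":
            hi = src[i + 1]
            if hi == "\\" and i + 2 < n:
                hi = src[i + 2]
                i += 3
            else:
                i += 2
            if hi < ch:
                raise GrammarLoadError(f"bad range {ch}-{hi} in [{src}]", line)
            ranges.append((ch, hi))
        else:
            ranges.append((ch, ch))
    if not ranges:
        raise GrammarLoadError("empty character class", line)
    return CharClass(tuple(ranges), src)


class _RuleParser:
    """Recursive-descent parser for one grammar file."""

    def __init__(self, text: str, name: str):
        self.tok = _Tok(text)
        self.g = Grammar(name=name, start_symbol="")
        self._fresh = 0

    def _fresh_rule(self, base: str, alts: list[Alternative]) -> str:
        self._fresh += 1
        name = f"{base}${self._fresh}"
        self.g.rules[name] = alts
        self.g.internal.add(name)
        return name

    def load(self) -> Grammar:
        while True:
            kind, val = self.tok.next_token()
            if kind == "eof":
                break
            if kind != "ident":
                raise GrammarLoadError(f"expected rule name, got {val!r}",
                                       self.tok.line)
            rule = val
            kind, val = self.tok.next_token()
            if (kind, val) != ("punct", "="):
                raise GrammarLoadError(f"expected '=' after {rule!r}",
                                       self.tok.line)
            alts, closer = self._alternatives(rule)
            if closer != ";":
                raise GrammarLoadError(f"expected ';' closing rule {rule!r}",
                                       self.tok.line)
            if rule in self.g.rules:
                raise GrammarLoadError(f"duplicate rule {rule!r}", self.tok.line)
            self.g.rules[rule] = alts
            if not self.g.start_symbol:
                self.g.start_symbol = rule
        if not self.g.start_symbol:
            raise GrammarLoadError("grammar defines no rules")
        self._validate()
        return self.g

    def _alternatives(self, rule: str) -> tuple[list[Alternative], str]:
        alts = [self._sequence(rule)]
        while True:
            kind, val = self.tok.next_token()
            if kind == "punct" and val == "|":
                alts.append(self._sequence(rule))
            elif kind == "punct" and val in ");":
                return alts, val
            elif kind == "eof":
                raise GrammarLoadError(f"unterminated rule {rule!r}",
                                       self.tok.line)
            else:
                raise GrammarLoadError(f"unexpected {val!r} in rule {rule!r}",
                                       self.tok.line)

    def _sequence(self, rule: str) -> Alternative:
        seq: list[Symbol] = []
        while True:
            save_pos, save_line = self.tok.pos, self.tok.line
            kind, val = self.tok.next_token()
            if kind == "lit":
                sym: Symbol = Lit(val)
            elif kind == "class":
                sym = _parse_class(val, self.tok.line)
            elif kind == "ident":
                sym = Ref(val)
            elif kind == "punct" and val == "(":
                alts, closer = self._alternatives(rule)
                if closer != ")":
                    raise GrammarLoadError(f"expected ')' in rule {rule!r}",
                                           self.tok.line)
                sym = Ref(self._fresh_rule(rule, alts))
            else:
                self.tok.pos, self.tok.line = save_pos, save_line
                return tuple(seq)
            # postfix operators
            while self.tok.peek() in "?*+":
                _, op = self.tok.next_token()
                if op == "?":
                    sym = Ref(self._fresh_rule(rule, [(sym,), ()]))
                elif op == "*":
                    rep = f"{rule}${self._fresh + 1}"
                    sym = Ref(self._fresh_rule(rule, [(sym, Ref(rep)), ()]))
                else:  # +
                    rep = self._fresh_rule(rule, [])
                    self.g.rules[rep] = [(sym, Ref(rep)), ()]
                    sym = Ref(self._fresh_rule(rule, [(sym, Ref(rep))]))
            seq.append(sym)

    def _validate(self) -> None:
        for rule, alts in self.g.rules.items():
            for alt in alts:
                for sym in alt:
                    if isinstance(sym, Ref) and sym.name not in self.g.rules:
                        raise GrammarLoadError(
                            f"rule {rule!r} references undefined "
                            f"nonterminal {sym.name!r}"
                        )
            for alt in alts:
                if alt and isinstance(alt[0], Ref) and alt[0].name == rule:
                    raise GrammarLoadError(
                        f"rule {rule!r} is directly left-recursive; "
                        "author it right-recursively"
                    )


def load_grammar(grammar_text: str, name: str = "") -> Grammar:
    """Load and validate a grammar from its textual definition."""
    text = unicodedata.normalize("NFC", grammar_text)
    return _RuleParser(text, name).load()


def load_builtin(dialect_file: str, name: str = "") -> Grammar:
    """Load one of the grammar files shipped under ``grammars/``."""
    from importlib.resources import files

    text = (files("liponorm") / "grammars" / dialect_file).read_text("utf-8")
    return load_grammar(text, name or dialect_file.rsplit(".", 1)[0])
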