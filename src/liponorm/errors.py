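"""Structured exceptions.

Every failure a caller can provoke with bad input is one of these; any
other exception escaping the public API is a bug (the no-crash fuzzing
test enforces this).
"""

from __future__ import annotations


class LiponormError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LiponormError):
    """A registry or grammar definition is inconsistent (packager bug)."""


class ContractViolation(LiponormError):
    """An API precondition was violated by the caller."""


class GrammarLoadError(ConfigurationError):
    """A grammar file failed to load (syntax, undefined or left-recursive rule)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class ParseFailure(LiponormError):
    """The input is not in the grammar's language.

    Carries the furthest offset reached by any derivation attempt and a
    summary of the terminals that were expected there.
    """

    def __init__(self, text: str, offset: int, expected: tuple[str, ...] = ()):
        self.text = text
        self.offset = min(offset, len(text))
        self.expected = tuple(sorted(set(expected)))
        hint = f", expected one of: {', '.join(self.expected)}" if self.expected else ""
        super().__init__(
            f"cannot parse {text!r}: failure at offset {self.offset}{hint}"
        )


class UnsupportedLipid(LiponormError):
    """Syntactically valid name whose chemistry the model cannot represent
    (unknown class or adduct token, triple bonds, ...)."""


class NotParseable(LiponormError):
    """No dialect grammar accepts the name; lists per-dialect failure offsets."""

    def __init__(self, text: str, failures: dict[str, int]):
        self.text = text
        self.failures = dict(failures)
        detail = "; ".join(f"{d}@{off}" for d, off in self.failures.items())
        super().__init__(f"no dialect accepts {text!r} ({detail})")


class LevelError(LiponormError):
    """Requested hierarchy level is finer than the information the lipid has."""
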