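"""Grammar loading and the backtracking parse engine."""

import pytest

from liponorm.errors import GrammarLoadError, ParseFailure
from liponorm.grammar import load_builtin, load_grammar
from liponorm.parser import parse, visit

PAREN = "S = '(' S ')' | '';"


class TestLoadGrammar:
    def test_recursive_single_rule(self):
        g = load_grammar(PAREN, "paren")
        assert g.start_symbol == "S"
        assert set(g.rules) == {"S"}

    def test_undefined_nonterminal_named_in_error(self):
        with pytest.raises(GrammarLoadError, match="T"):
            load_grammar("S = T;")

    def test_direct_left_recursion_rejected(self):
        with pytest.raises(GrammarLoadError, match="left-recursive"):
            load_grammar("S = S 'a' | 'a';")

    def test_syntax_error_reports_line(self):
        with pytest.raises(GrammarLoadError, match="line 2"):
            load_grammar("a = 'x';\nb = ; ;")

    def test_shipped_shorthand_grammar_loads_and_derives(self):
        g = load_builtin("shorthand2020.g")
        tree = parse(g, "PE 16:1(6Z)/16:0;5OH[R],8OH[S];3oxo")
        assert tree.matched() == "PE 16:1(6Z)/16:0;5OH[R],8OH[S];3oxo"


class TestParse:
    def test_nesting_depth(self):
        g = load_grammar(PAREN)
        assert parse(g, "((()))").depth() == 4

    def test_rejection_with_furthest_offset(self):
        g = load_grammar(PAREN)
        with pytest.raises(ParseFailure) as exc:
            parse(g, "(()")
        assert exc.value.offset == 3

    def test_leaf_spans_reconstruct_input(self):
        g = load_builtin("shorthand2020.g")
        text = "TG 16:0;5O(FA 16:0)/18:1(9Z)/18:1(9Z)"
        tree = parse(g, text)
        leaves = tree.leaves()
        assert "".join(leaf.text for leaf in leaves) == text
        assert [leaf.start for leaf in leaves] == sorted(
            leaf.start for leaf in leaves)

    def test_nested_chain_inside_functional_group(self):
        g = load_builtin("shorthand2020.g")
        tree = parse(g, "TG 16:0;5O(FA 16:0)/18:1(9Z)/18:1(9Z)")
        branch = tree.find("acyl_branch")
        assert branch is not None
        assert branch.find("core_chain") is not None

    def test_backtracks_across_rule_boundaries(self):
        # ordered-choice-only (PEG) parsing would commit 'a' 'a' and fail
        g = load_grammar("s = a 'b'; a = 'a' 'a' | 'a';")
        assert parse(g, "ab").matched() == "ab"
        assert parse(g, "aab").matched() == "aab"

    def test_deterministic_tree_for_ambiguous_grammar(self):
        g = load_grammar("s = x | y; x = 'a'; y = 'a';")
        t1, t2 = parse(g, "a"), parse(g, "a")
        assert t1.children[0].label == "x"  # first-listed alternative wins
        assert t1 == t2


class TestVisit:
    def test_counting_handler(self):
        g = load_grammar(PAREN)
        tree = parse(g, "((()))")
        count = visit(tree, {"S": lambda node, n: n + 1}, 0)
        assert count == 4  # three pairs plus the empty derivation

    def test_chain_spec_handler_builds_chain(self):
        from liponorm.dialects._common import build_core_chain

        g = load_builtin("shorthand2020.g")
        tree = parse(g, "FA 16:0;3OH")
        chain = build_core_chain(tree.find("core_chain"))
        assert (chain.num_carbons, chain.num_dbe) == (16, 0)
        (group,) = chain.functional_groups
        assert (group.name, group.position) == ("OH", 3)

    def test_no_handlers_returns_initial_state(self):
        g = load_grammar(PAREN)
        state = object()
        assert visit(parse(g, "()"), {}, state) is state

    def test_enter_exit_ordering(self):
        g = load_grammar(PAREN)
        events = []
        visit(parse(g, "(())"), {
            "S": (lambda n, s: events.append(("in", n.start)),
                  lambda n, s: events.append(("out", n.start))),
        })
        ins = [e for e in events if e[0] == "in"]
        outs = [e for e in events if e[0] == "out"]
        assert len(ins) == len(outs) == 3
        assert events[0][0] == "in" and events[-1][0] == "out"
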