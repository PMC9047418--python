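"""Elemental arithmetic: group structure, Hill formatting, masses."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liponorm.elements import (
    ElementCounts,
    add_elements,
    formula_string,
    monoisotopic_mass,
    parse_formula,
)
from liponorm.errors import ConfigurationError, ContractViolation

counts = st.fixed_dictionaries(
    {},
    optional={sym: st.integers(-20, 40) for sym in "CHNOPS"},
).map(ElementCounts)


class TestAddElements:
    def test_identity_and_cancellation(self):
        assert add_elements(ElementCounts({"C": 2, "H": 4}), ElementCounts()) \
            == ElementCounts({"C": 2, "H": 4})
        summed = add_elements(ElementCounts({"C": 1, "H": -2}),
                              ElementCounts({"C": 1, "H": 2}))
        assert summed == ElementCounts({"C": 2})
        assert "H" not in summed

    def test_inputs_unmodified(self):
        a = ElementCounts({"C": 1})
        b = ElementCounts({"C": 2})
        add_elements(a, b)
        assert a == ElementCounts({"C": 1}) and b == ElementCounts({"C": 2})

    def test_unknown_element_rejected(self):
        with pytest.raises(ConfigurationError):
            ElementCounts({"Xx": 1})

    @settings(max_examples=200, deadline=None)
    @given(a=counts, b=counts, c=counts)
    def test_commutative_group_over_deltas(self, a, b, c):
        assert a + b == b + a
        assert (a + b) + c == a + (b + c)
        assert a + ElementCounts() == a
        assert a + (a * -1) == ElementCounts()


class TestFormulaString:
    @pytest.mark.parametrize("ec,expected", [
        ({"C": 16, "H": 32, "O": 2}, "C16H32O2"),
        ({"H": 2, "O": 1}, "H2O"),
        ({"C": 39, "H": 76, "N": 1, "O": 8, "P": 1}, "C39H76NO8P"),
        ({"C": 1}, "C"),
        ({}, ""),
    ])
    def test_hill_order(self, ec, expected):
        assert formula_string(ElementCounts(ec)) == expected

    def test_negative_count_is_contract_violation(self):
        with pytest.raises(ContractViolation):
            formula_string(ElementCounts({"C": -1}))

    @settings(max_examples=200, deadline=None)
    @given(ec=st.fixed_dictionaries(
        {}, optional={sym: st.integers(1, 99) for sym in "CHNOPS"},
    ).map(ElementCounts))
    def test_round_trip_with_parse(self, ec):
        assert parse_formula(formula_string(ec)) == ec


class TestMonoisotopicMass:
    def test_empty_is_zero(self):
        assert monoisotopic_mass(ElementCounts(), 0) == 0.0

    def test_palmitic_acid(self):
        mass = monoisotopic_mass(ElementCounts({"C": 16, "H": 32, "O": 2}))
        assert mass == pytest.approx(256.2402, abs=5e-4)

    def test_protonated_ion_loses_an_electron(self):
        neutral = monoisotopic_mass(ElementCounts({"C": 16, "H": 32, "O": 2}))
        proton = monoisotopic_mass(ElementCounts({"H": 1}))
        mz = monoisotopic_mass(ElementCounts({"C": 16, "H": 33, "O": 2}), +1)
        assert mz == pytest.approx(neutral + proton - 0.000548580, abs=1e-6)

    def test_doubly_charged_divides_by_charge(self):
        ec = ElementCounts({"C": 10, "H": 22})
        assert monoisotopic_mass(ec, 2) == pytest.approx(
            (monoisotopic_mass(ec) - 2 * 0.000548580) / 2)

    @settings(max_examples=100, deadline=None)
    @given(a=st.fixed_dictionaries(
        {}, optional={sym: st.integers(0, 50) for sym in "CHNOPS"},
    ).map(ElementCounts), b=st.fixed_dictionaries(
        {}, optional={sym: st.integers(0, 50) for sym in "CHNOPS"},
    ).map(ElementCounts))
    def test_linearity_at_charge_zero(self, a, b):
        assert monoisotopic_mass(a + b) == pytest.approx(
            monoisotopic_mass(a) + monoisotopic_mass(b), abs=1e-9)
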