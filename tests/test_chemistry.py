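"""Sum formulas, masses, and atom conservation under aggregation."""

import pytest

from liponorm import (
    formula_of,
    lipid_elements,
    parse_name,
    parse_shorthand,
    sum_formula,
)
from liponorm.model import LipidLevel as L
from liponorm.normalize import aggregate_to_level

# name -> formula, verified independently (RDKit cross-check below for a
# subset; the rest are textbook reference compositions)
KNOWN_FORMULAS = {
    "FA 16:0": "C16H32O2",                       # palmitic acid
    "FA 18:1(9Z)": "C18H34O2",                   # oleic acid
    "TG 16:0/18:1(9Z)/18:1(9Z)": "C55H102O6",
    "PC 16:0/18:1(9Z)": "C42H82NO8P",            # POPC
    "PE 16:0/18:1(9Z)": "C39H76NO8P",
    "PS 16:0/18:1(9Z)": "C40H76NO10P",
    "PG 16:0/18:1(9Z)": "C40H77O10P",
    "PI 16:0/18:1(9Z)": "C43H81O13P",
    "PA 16:0/18:1(9Z)": "C37H71O8P",
    "LPC 16:0": "C24H50NO7P",
    "Cer 18:1;O2/16:0": "C34H67NO3",             # d18:1/16:0 ceramide
    "SM 34:1;O2": "C39H79N2O6P",
    "CE 16:0": "C43H76O2",                       # cholesteryl palmitate
    "NAE 16:0": "C18H37NO2",                     # palmitoyl ethanolamide
    "PC O-16:0/18:1(9Z)": "C42H84NO7P",
    "TG 16:0;5O(FA 16:0)/18:1(9Z)/18:1(9Z)": "C71H132O8",
}

# SMILES for the independent RDKit atom-count oracle
SMILES = {
    "FA 16:0": "CCCCCCCCCCCCCCCC(=O)O",
    "FA 18:1(9Z)": "CCCCCCCC/C=C\\CCCCCCCC(=O)O",
    "TG 16:0/18:1(9Z)/18:1(9Z)":
        "CCCCCCCCCCCCCCCC(=O)OCC(OC(=O)CCCCCCC/C=C\\CCCCCCCC)"
        "COC(=O)CCCCCCC/C=C\\CCCCCCCC",
    "NAE 16:0": "CCCCCCCCCCCCCCCC(=O)NCCO",
    "PE 16:0/18:1(9Z)":
        "CCCCCCCCCCCCCCCC(=O)OCC(OC(=O)CCCCCCC/C=C\\CCCCCCCC)"
        "COP(=O)(O)OCCN",
}


class TestSumFormula:
    @pytest.mark.parametrize("name,expected", sorted(KNOWN_FORMULAS.items()))
    def test_reference_compositions(self, name, expected):
        assert formula_of(parse_shorthand(name)) == expected

    @pytest.mark.parametrize("name", sorted(SMILES))
    def test_against_rdkit_oracle(self, name):
        from rdkit import Chem
        from rdkit.Chem.rdMolDescriptors import CalcMolFormula

        want = CalcMolFormula(Chem.AddHs(Chem.MolFromSmiles(SMILES[name])))
        assert formula_of(parse_shorthand(name)) == want

    def test_species_equals_complete_structure(self, pe_lipid):
        fine = lipid_elements(pe_lipid)
        for level in [L.FULL_STRUCTURE, L.STRUCTURE_DEFINED, L.SN_POSITION,
                      L.MOLECULAR_SPECIES, L.SPECIES]:
            assert lipid_elements(aggregate_to_level(pe_lipid, level)) == fine

    def test_below_species_has_no_formula(self):
        from liponorm.errors import ContractViolation

        lipid = parse_shorthand("PE").lipid
        with pytest.raises(ContractViolation):
            lipid_elements(lipid)


class TestMasses:
    def test_neutral_mass_of_palmitic_acid(self):
        _, mass, mz = sum_formula(parse_shorthand("FA 16:0"))
        assert mass == pytest.approx(256.2402, abs=5e-4)
        assert mz is None

    def test_protonated_mz(self):
        _, mass, mz = sum_formula(parse_shorthand("PC 16:0/18:1(9Z)[M+H]1+"))
        assert mz == pytest.approx(mass + 1.007276, abs=1e-4)

    def test_deprotonated_mz(self):
        _, mass, mz = sum_formula(parse_shorthand("PE 16:0/18:1(9Z)[M-H]1-"))
        assert mz == pytest.approx(mass - 1.007276, abs=1e-4)

    def test_doubly_protonated_mz_is_half(self):
        _, mass, mz = sum_formula(parse_shorthand("PC 16:0/18:1(9Z)[M+2H]2+"))
        assert mz == pytest.approx((mass + 2 * 1.007276) / 2, abs=1e-4)

    def test_ammonium_adduct(self):
        _, mass, mz = sum_formula(
            parse_shorthand("TG 16:0/18:1(9Z)/18:1(9Z)[M+NH4]1+"))
        assert mz == pytest.approx(mass + 18.033823, abs=1e-4)


class TestCrossDialectConsistency:
    @pytest.mark.parametrize("a,b", [
        ("PE(16:1(6Z)/16:0)", "PE 16:1(6Z)/16:0"),
        ("TAG 16:0-18:1-18:1", "TG 16:0_18:1_18:1"),
        ("PC(16:0/0:0)", "PC 16:0/0:0"),
        ("Cer(d18:1/16:0)", "Cer 18:1;O2/16:0"),
    ])
    def test_same_lipid_same_formula_and_name(self, a, b):
        la, lb = parse_name(a), parse_name(b)
        assert la.lipid == lb.lipid
        assert formula_of(la) == formula_of(lb)
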