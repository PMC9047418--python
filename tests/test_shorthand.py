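"""Shorthand-2020 dialect: structures, level detection, adducts."""

import pytest

from liponorm import parse_shorthand
from liponorm.errors import ParseFailure, UnsupportedLipid
from liponorm.model import BondType, LipidLevel as L


class TestStructures:
    def test_oxygenated_pe_complete_structure(self, pe_lipid):
        assert pe_lipid.level is L.COMPLETE_STRUCTURE
        assert pe_lipid.headgroup.class_name == "PE"
        sn1, sn2 = pe_lipid.chains
        assert (sn1.num_carbons, sn1.num_dbe) == (16, 1)
        assert sn1.db_positions == {6: "Z"}
        by_pos = {g.position: g for g in sn2.functional_groups}
        assert {p: (g.name, g.stereo) for p, g in by_pos.items()} == {
            5: ("OH", "R"), 8: ("OH", "S"), 3: ("oxo", ""),
        }

    def test_species_level_aggregate(self):
        lipid = parse_shorthand("PE 32:2;O3").lipid
        assert lipid.level is L.SPECIES
        assert not lipid.chains
        agg = lipid.aggregated_info
        assert (agg.total_carbons, agg.total_dbe, agg.total_oxygens) == (32, 2, 3)

    def test_nested_acyl_branch(self):
        lipid = parse_shorthand("TG 16:0;5O(FA 16:0)/18:1(9Z)/18:1(9Z)").lipid
        (branch,) = lipid.chains[0].functional_groups
        assert branch.name == "O" and branch.position == 5
        assert branch.attachment.num_carbons == 16
        assert lipid.chains[1].db_positions == {9: "Z"}

    def test_ether_prefixes(self):
        plasmanyl = parse_shorthand("PC O-16:0/18:1(9Z)").lipid
        plasmenyl = parse_shorthand("PC P-16:0/18:1(9Z)").lipid
        assert plasmanyl.chains[0].bond_type is BondType.ETHER_PLASMANYL
        assert plasmenyl.chains[0].bond_type is BondType.ETHER_PLASMENYL

    def test_sphingoid_slots(self):
        lipid = parse_shorthand("Cer 18:1;O2/16:0").lipid
        assert lipid.chains[0].bond_type is BondType.LCB
        assert lipid.chains[0].agg_oxygens == 2
        assert lipid.chains[1].bond_type is BondType.AMIDE

    def test_empty_sn_slot(self):
        lipid = parse_shorthand("PC 16:0/0:0").lipid
        assert lipid.chains[1].is_empty

    def test_unknown_class_is_unsupported(self):
        with pytest.raises(UnsupportedLipid):
            parse_shorthand("QQQ 16:0/18:1")

    def test_malformed_name_is_parse_error(self):
        with pytest.raises(ParseFailure):
            parse_shorthand("PE 16:1(6Z/16:0")

    def test_too_many_chains_rejected(self):
        with pytest.raises(UnsupportedLipid):
            parse_shorthand("PC 16:0/16:0/16:0")

    def test_double_bond_position_outside_chain_rejected(self):
        with pytest.raises(UnsupportedLipid):
            parse_shorthand("PC 4:1(9Z)/16:0")


class TestLevelDetection:
    @pytest.mark.parametrize("name,level", [
        ("PE 16:1(6Z)/16:0;5OH[R],8OH[S];3oxo", L.COMPLETE_STRUCTURE),
        ("PE 16:1(6Z)/16:0;5OH,8OH;3oxo", L.FULL_STRUCTURE),
        ("PE 16:1(6)/16:0;(OH)2;oxo", L.STRUCTURE_DEFINED),
        ("PE 16:1/16:1;O3", L.SN_POSITION),
        ("PE 16:1_16:1;O3", L.MOLECULAR_SPECIES),
        ("PE 32:2;O3", L.SPECIES),
        ("PE 16:0/18:1", L.SN_POSITION),
        ("FA 18:0;5Me", L.FULL_STRUCTURE),
    ])
    def test_finest_supported_level(self, name, level):
        assert parse_shorthand(name).lipid.level is level

    def test_deleting_information_drops_level_monotonically(self):
        ladder = [
            "PE 16:1(6Z)/16:0;5OH[R],8OH[S];3oxo",
            "PE 16:1(6Z)/16:0;5OH,8OH;3oxo",
            "PE 16:1(6)/16:0;(OH)2;oxo",
            "PE 16:1/16:1;O3",
            "PE 16:1_16:1;O3",
            "PE 32:2;O3",
        ]
        levels = [parse_shorthand(n).lipid.level for n in ladder]
        assert levels == sorted(levels, reverse=True)
        assert len(set(levels)) == len(levels)


class TestAdducts:
    def test_protonation(self):
        la = parse_shorthand("PE 32:2;O3[M+H]1+")
        assert la.adduct.charge == +1
        assert la.adduct.element_delta == {"H": 1}

    def test_deprotonation(self):
        la = parse_shorthand("PE 32:2;O3[M-H]1-")
        assert la.adduct.charge == -1
        assert la.adduct.element_delta == {"H": -1}

    def test_unknown_adduct_token(self):
        with pytest.raises(UnsupportedLipid):
            parse_shorthand("PE 32:2;O3[M+Xx]1+")

    def test_charge_sign_must_match_token(self):
        with pytest.raises(UnsupportedLipid):
            parse_shorthand("PE 32:2;O3[M+H]1-")
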