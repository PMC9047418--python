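"""Systematic IUPAC-IUB fatty acyl names."""

import pytest

from liponorm import parse_iupac_fa, print_name
from liponorm.dialects.iupac import MULTIPLIERS
from liponorm.errors import ParseFailure, UnsupportedLipid
from liponorm.model import LipidLevel as L

from conftest import IUPAC_TRANSLATIONS


class TestStandardization:
    @pytest.mark.parametrize("name,shorthand", IUPAC_TRANSLATIONS)
    def test_translates_to_exact_shorthand(self, name, shorthand):
        assert print_name(parse_iupac_fa(name).lipid) == shorthand

    @pytest.mark.parametrize("name,shorthand", IUPAC_TRANSLATIONS)
    def test_output_reparses_in_shorthand_dialect(self, name, shorthand):
        from liponorm import parse_shorthand

        assert print_name(parse_shorthand(shorthand).lipid) == shorthand

    @pytest.mark.parametrize("name,carbons", [
        ("5-methyl-octadecanoic acid", 18),
        ("2-docosyl-3-hydroxy-28,29-epoxy-30-methyl-pentacontanoic acid", 50),
        ("11R-hydroxy-9,15-dioxo-2,3,4,5-tetranor-prostan-1,20-dioic acid", 15),
        ("N-((±)-8,9-dihydroxy-5Z,11Z,14Z-eicosatrienoyl)-ethanolamine", 20),
    ])
    def test_main_chain_carbon_counts(self, name, carbons):
        assert parse_iupac_fa(name).lipid.chains[0].num_carbons == carbons


class TestMultiplierLexicon:
    def test_every_plain_acid_parses_to_its_carbon_count(self):
        # brute-force lexicon oracle over the full 1..60 range
        for stem, count in sorted(MULTIPLIERS.items()):
            lipid = parse_iupac_fa(f"{stem}anoic acid").lipid
            assert lipid.chains[0].num_carbons == count, stem

    def test_composite_stems_resolve_by_longest_match(self):
        assert parse_iupac_fa("tetracosanoic acid").lipid.chains[0].num_carbons == 24
        assert parse_iupac_fa("tetradecanoic acid").lipid.chains[0].num_carbons == 14
        assert parse_iupac_fa("decanoic acid").lipid.chains[0].num_carbons == 10


class TestRenumbering:
    def test_tetranor_prostane_locants_fit_reduced_skeleton(self):
        name = "11R-hydroxy-9,15-dioxo-2,3,4,5-tetranor-prostan-1,20-dioic acid"
        chain = parse_iupac_fa(name).lipid.chains[0]
        assert chain.num_carbons == 15
        (cycle,) = chain.cycles
        assert (cycle.start_position, cycle.end_position) == (4, 8)
        assert cycle.cycle_carbons == 5
        in_ring = {(g.name, g.position) for g in cycle.internal_groups}
        assert in_ring == {("OH", 7), ("oxo", 5)}
        outside = {(g.name, g.position) for g in chain.functional_groups}
        assert outside == {("oxo", 11), ("COOH", 15)}
        assert all(g.position <= 15
                   for g in chain.functional_groups + cycle.internal_groups)

    def test_nor_locant_must_exist(self):
        with pytest.raises(UnsupportedLipid):
            parse_iupac_fa("21,22-dinor-octadecanoic acid")


class TestGrammarCoverage:
    @pytest.mark.parametrize("name,shorthand", [
        ("octadecanoic acid", "FA 18:0"),
        ("octadec-9-enoic acid", "FA 18:1(9)"),
        ("9Z-octadecenoic acid", "FA 18:1(9Z)"),
        ("octadeca-9,12-dienoic acid", "FA 18:2(9,12)"),
        ("hexadecanedioic acid", "FA 15:0;15COOH"),
        ("12-hydroperoxy-octadecanoic acid", "FA 18:0;12OOH"),
        ("N-(hexadecanoyl)-ethanolamine", "NAE 16:0"),
    ])
    def test_common_patterns(self, name, shorthand):
        assert print_name(parse_iupac_fa(name).lipid) == shorthand

    def test_racemic_marker_drops_stereo(self):
        la = parse_iupac_fa(
            "N-((±)-8,9-dihydroxy-5Z,11Z,14Z-eicosatrienoyl)-ethanolamine")
        assert all(g.stereo == "" for g in la.lipid.chains[0].functional_groups)

    def test_stereo_descriptor_kept_but_level_stays_full(self):
        la = parse_iupac_fa("11R-hydroxy-9,15-dioxo-2,3,4,5-tetranor-"
                            "prostan-1,20-dioic acid")
        assert la.lipid.level is L.FULL_STRUCTURE
        stereo = {g.stereo for g in la.lipid.chains[0].cycles[0].internal_groups}
        assert "R" in stereo

    def test_triple_bond_is_unrepresentable(self):
        with pytest.raises(UnsupportedLipid, match="triple"):
            parse_iupac_fa("octadec-9-ynoic acid")

    def test_epoxy_must_bridge_adjacent_carbons(self):
        with pytest.raises(UnsupportedLipid):
            parse_iupac_fa("5,9-epoxy-octadecanoic acid")

    def test_nonsense_rejected(self):
        with pytest.raises(ParseFailure):
            parse_iupac_fa("palmitic acid")
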