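import pytest

# the oxygenated PE used throughout the hierarchy documentation, with
# its printed form at every level
PE_COMPLETE = "PE 16:1(6Z)/16:0;5OH[R],8OH[S];3oxo"
PE_LADDER = {
    "COMPLETE_STRUCTURE": "PE 16:1(6Z)/16:0;5OH[R],8OH[S];3oxo",
    "FULL_STRUCTURE": "PE 16:1(6Z)/16:0;5OH,8OH;3oxo",
    "STRUCTURE_DEFINED": "PE 16:1(6)/16:0;(OH)2;oxo",
    "SN_POSITION": "PE 16:1/16:1;O3",
    "MOLECULAR_SPECIES": "PE 16:1_16:1;O3",
    "SPECIES": "PE 32:2;O3",
    "CLASS": "PE",
    "CATEGORY": "GP",
}

# systematic IUPAC-IUB names and their standardized shorthand
IUPAC_TRANSLATIONS = [
    ("5-methyl-octadecanoic acid", "FA 18:0;5Me"),
    ("2-docosyl-3-hydroxy-28,29-epoxy-30-methyl-pentacontanoic acid",
     "FA 50:0;2(22:0);30Me;28Ep;3OH"),
    ("11R-hydroxy-9,15-dioxo-2,3,4,5-tetranor-prostan-1,20-dioic acid",
     "FA 15:0;[4-8cy5:0;7OH;5oxo];11oxo;15COOH"),
    ("N-((±)-8,9-dihydroxy-5Z,11Z,14Z-eicosatrienoyl)-ethanolamine",
     "NAE 20:3(5Z,11Z,14Z);8OH,9OH"),
]


@pytest.fixture
def pe_lipid():
    from liponorm import parse_shorthand

    return parse_shorthand(PE_COMPLETE).lipid
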