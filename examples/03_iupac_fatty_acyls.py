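"""Standardize systematic IUPAC-IUB fatty acyl names.

Branches become nested chain attachments, epoxy locant pairs collapse
to one bridging group, nor-prefixes remove skeleton carbons with
renumbering (the prostane ring span moves accordingly), and dioic acids
express the far carboxyl as a COOH group.
"""

import liponorm

NAMES = [
    "5-methyl-octadecanoic acid",
    "2-docosyl-3-hydroxy-28,29-epoxy-30-methyl-pentacontanoic acid",
    "11R-hydroxy-9,15-dioxo-2,3,4,5-tetranor-prostan-1,20-dioic acid",
    "N-((±)-8,9-dihydroxy-5Z,11Z,14Z-eicosatrienoyl)-ethanolamine",
]

for name in NAMES:
    la = liponorm.parse_iupac_fa(name)
    print(f"{name}\n    -> {liponorm.print_name(la.lipid)}  "
          f"({liponorm.formula_of(la)})\n")
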