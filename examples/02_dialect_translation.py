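"""Translate names from several nomenclature dialects into one
standardized shorthand.

The same molecule written the LIPID MAPS way, the HMDB way or the
legacy Goslin way lands on the same structure and therefore the same
normalized name.
"""

import liponorm

NAMES = [
    "PE 16:1(6Z)/16:0",          # updated shorthand
    "PE(16:1(6Z)/16:0)",         # LIPID MAPS
    "Cer(d18:1/16:0)",           # LIPID MAPS sphingoid d-prefix
    "TAG 16:0-18:1-18:1",        # legacy Goslin
    "LysoPC(16:0)",              # HMDB
    "PC(34:1)",                  # SwissLipids species total
]

for name in NAMES:
    la = liponorm.parse_name(name)
    print(f"{name:28s} [{la.source_dialect:12s}] -> "
          f"{liponorm.print_name(la.lipid)}")
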