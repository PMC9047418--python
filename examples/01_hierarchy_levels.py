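"""Parse one fully annotated lipid name and print it at every level.

The complete-structure name below carries stereochemistry ([R]/[S], Z),
group positions, sn assignment and class identity; each coarser level
discards one kind of information, down to the bare category.
"""

import liponorm
from liponorm import LipidLevel

NAME = "PE 16:1(6Z)/16:0;5OH[R],8OH[S];3oxo"

la = liponorm.parse_shorthand(NAME)
print(f"input: {NAME}")
print(f"detected level: {la.lipid.level.name}\n")
for level in reversed(LipidLevel):
    print(f"{level.name:20s} {liponorm.print_name(la.lipid, level)}")
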