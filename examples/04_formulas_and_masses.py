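"""Sum formulas, neutral masses and adduct m/z values.

The composition is head-group scaffold + free chains - one water per
ester/ether/amide bond; adduct atoms and electron bookkeeping give the
m/z of the ion.
"""

import liponorm

for name in [
    "FA 16:0",
    "TG 16:0/18:1(9Z)/18:1(9Z)[M+NH4]1+",
    "PC 16:0/18:1(9Z)[M+H]1+",
    "PE 32:2;O3[M-H]1-",
]:
    la = liponorm.parse_name(name)
    ec, mass, mz = liponorm.sum_formula(la)
    line = f"{name:40s} {liponorm.formula_string(ec):14s} M={mass:.4f}"
    if mz is not None:
        line += f"  m/z={mz:.4f} ({la.adduct.name}, {la.adduct.charge:+d})"
    print(line)
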