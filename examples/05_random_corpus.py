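"""Generate a reproducible corpus of valid shorthand names and verify
the parse -> print -> parse fixed point on all of them.

This is the desk-scale robustness check used by the test suite; the
generator samples random structures (including nested acyl/alkyl
branches) and prints them at random hierarchy levels.
"""

import liponorm

names = liponorm.generate_fixture_names(seed=42, n=25, max_depth=2)
ok = 0
for name in names:
    assert liponorm.print_name(liponorm.parse_shorthand(name).lipid) == name
    ok += 1
print(f"{ok}/{len(names)} generated names round-trip; first few:")
for name in names[:6]:
    print("   ", name)
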