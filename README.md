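# liponorm

Grammar-based parsing and normalization of mass-spectrometry-derived
lipid names.

Lipidomics datasets name the same molecule many ways: the updated
shorthand nomenclature (`PE 16:1(6Z)/16:0;5OH[R],8OH[S];3oxo`), the
older parenthesized style used by LIPID MAPS and HMDB
(`PE(16:1(6Z)/16:0)`, `Cer(d18:1/16:0)`), hyphen-separated legacy names
(`TAG 16:0-18:1-18:1`), or fully systematic IUPAC-IUB fatty acyl names
(`5-methyl-octadecanoic acid`). Integrating and re-analyzing such data
requires translating all of these into one standardized name — at a
*chosen* level of structural certainty — and computing sum formulas and
adduct masses along the way. liponorm does that, for tool builders and
database curators who need it as a library call rather than a web form.

## How it works

Each nomenclature dialect is described by a context-free grammar
shipped as a plain-text file (`src/liponorm/grammars/*.g`). Lipid names
nest — an acyl branch inside a functional group is itself a complete
chain specification, as in `TG 16:0;5O(FA 16:0)/18:1(9Z)/18:1(9Z)` — so
regular expressions cannot recognize them in general; a memoized
backtracking parser over the grammar can, to arbitrary depth, and
rejects malformed names with the offset of the failure instead of
passing wrong annotations through.

Parsed names land in a common structural model ordered by an
eight-level hierarchy of structural knowledge:

category < class < species < molecular species < sn-position <
structure defined < full structure < complete structure

Aggregating downward discards information in a defined order (stereo →
positions/configurations → group identity, folded into the
double-bond-equivalent count and an oxygen tally → sn assignment →
per-chain identity). The sum formula is assembled as head-group
scaffold + free chains − one H₂O per ester/ether/amide bond, and is
invariant under aggregation.

## Worked example

```python
>>> import liponorm
>>> la = liponorm.parse_name("PE 16:1(6Z)/16:0;5OH[R],8OH[S];3oxo")
>>> la.lipid.level.name
'COMPLETE_STRUCTURE'
>>> liponorm.print_name(la.lipid, liponorm.LipidLevel.SPECIES)
'PE 32:2;O3'
>>> liponorm.formula_of(la)
'C37H70NO11P'
>>> liponorm.normalize_name("11R-hydroxy-9,15-dioxo-2,3,4,5-tetranor-prostan-1,20-dioic acid")
'FA 15:0;[4-8cy5:0;7OH;5oxo];11oxo;15COOH'
```

`PE 32:2;O3` reads: a phosphatidylethanolamine whose two chains total
32 carbons, 2 double-bond equivalents (one C=C plus the oxo group) and
3 functional-group oxygens. The systematic prostane name is renumbered
after removal of carbons 2–5, so the cyclopentane ring spans positions
4–8 of the 15-carbon main chain and the far carboxyl prints as
`15COOH`.

The `examples/` directory holds one short script per capability
(hierarchy levels, dialect translation, IUPAC standardization, masses,
random-corpus round-trips); each prints what it computes. The same
functionality is available from the shell:

```
liponorm --name "PE 16:1(6Z)/16:0;5OH[R],8OH[S];3oxo" --level species
liponorm --input names.tsv --output normalized.tsv --strict
```

Table input is TSV with a `lipid_name` column; unparsable rows are kept
with `status=FAILED` and an error message, never dropped.

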