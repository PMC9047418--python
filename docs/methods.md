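# Methods

## The structural model and its hierarchy

A lipid name encodes graded structural knowledge. The model mirrors
this with an ordered eight-level enumeration (category, class, species,
molecular species, sn-position, structure defined, full structure,
complete structure); every `Lipid` carries exactly one level, and
operations may only move it toward coarser levels — information is
discarded, never invented (`LevelError` otherwise).

A `Lipid` is a head group plus chains. A `Chain` records carbon count,
carbon–carbon double-bond count with optional positions and Z/E
configurations, its bond to the scaffold (ester, plasmanyl O- ether,
plasmenyl P- vinyl ether, amide, sphingoid base, or free), functional
groups, and carbocycles. A `FunctionalGroup` may carry a nested chain
attachment — the recursive case that makes the nomenclature
context-free rather than regular. At species level the chains are
replaced by three totals (carbons, double-bond equivalents, oxygens)
plus the bond types of the occupied slots, which is all the arithmetic
below needs.

## Parsing

Grammars are plain-text EBNF-like files (one per dialect under
`grammars/`): `rule = alternatives ;`, quoted literals, character
classes, grouping, postfix `?/*/+` (desugared at load time into fresh
right-recursive rules). The loader validates that every referenced
nonterminal is defined and rejects direct left recursion; grammars are
authored right-recursively. Whitespace is significant — the space
between class token and chain list is a terminal. Input is normalized
to Unicode NFC, so `±` in racemic markers is a single terminal.

The engine is a memoized backtracking recognizer: per (nonterminal,
offset) it enumerates every reachable end offset, keeping for each end
the first derivation in rule order. This yields two properties the
package relies on:

* **determinism** — an ambiguous string still gets exactly one tree
  (first-listed alternative wins), so identical input always produces
  identical output;
* **completeness across rule boundaries** — a nonterminal's match
  length is chosen so that the *whole* input parses, which plain
  ordered-choice (PEG) parsing cannot guarantee and which the nested
  branch syntax needs.

Failures carry the furthest offset any derivation reached and the
terminals expected there. Every error a caller can provoke is a
structured exception (`ParseFailure`, `UnsupportedLipid`,
`NotParseable`, `LevelError`); the fuzzing test holds the package to
this.

Left recursion hidden behind nullable prefixes is curtailed rather than
detected at load time; none of the shipped grammars uses it.

## Level detection and canonicalization

The finest level a name supports is read off its tokens: `_`
separators cap at molecular species; aggregate oxygen suffixes
(`;O3`, or legacy `d18:1` / `;2` hydroxyl counts, whose positions are
genuinely unknown) cap at sn-position; named groups or double-bond
positions grant structure defined; full positions with configurations
grant full structure; R/S stereo grants complete structure. A single
chain given for a multi-chain class is a species-level total. After
detection the parsed structure is folded down to exactly that level, so
a name mixing aggregated and positional fragments cannot smuggle finer
information through printing.

One degeneracy is inherent to the nomenclature: for single-chain
classes the printed strings at species through sn-position coincide
("FA 16:0"), so re-parsing a species-level print of such a lipid
detects sn-position. The round-trip properties are therefore stated on
the printed string (a fixed point), and the printed-level-equality
property on multi-chain examples.

## Printing

Functional-group clauses print in a fixed precedence — carbocycles,
then acyl/alkyl branches by position, then simple groups in the order
Me, Et, Ep, OMe, OH, OOH, NH2, SH, oxo, COOH (names outside the list
last, alphabetically); within a clause, entries sort by ascending
position. This order is the one consistent with the worked examples of
the nomenclature; nothing in the sources pins down a rule, so it is
fixed here and tested. At structure-defined level identical groups
merge to the counted form `(OH)2`; double-bond positions print bare.
Chains at molecular-species level sort ascending by (carbons, DBE,
oxygens, bond type) — the published examples show only equal chains, so
the tiebreak is this package's choice. The oxygen tally prints `;O`
for one oxygen and `;O<n>` otherwise, attached to its owning chain at
chain-resolved levels and to the species total otherwise. Cycles keep
their span at structure-defined level (the span *is* the cycle's
identity), while their internal groups lose positions.

## Elemental arithmetic

Compositions are signed element tallies over C, H, N, O, P, S (plus
Na, K, Cl for adducts only). A chain starts from the saturated
hydrocarbon CₙH₂ₙ₊₂, loses 2 H per C=C bond, ring closure and ring
double bond, gains its bond-type atoms (carboxyl +O₂ with its C=O for
acyl chains and the free fatty-acid case, +O for ethers — plasmenyl
also spending the vinyl double bond — and +N+H for sphingoid bases),
then applies every functional group's **complete** atom delta
(hydrogens included: OH = +O, oxo = +O−2H, Me = +C+2H, Ep = +O−2H,
OOH = +2O, COOH = +C+2O, ester branch = +2O−4H plus the attached
chain, alkyl branch = −2H plus the attached chain). One water is
removed per ester/ether/amide bond formed. Head-group templates are the
scaffold compositions without chains (glycerol, glycerophospho-X,
ethanolamine, cholesterol, phosphocholine-over-ceramide, ...).

Separately from the atom deltas, each group carries a
`dbe_contribution` used only for display aggregation (oxo, Ep, COOH
and the ester-branch carbonyl count 1; branches add their attachment's
double bonds). Keeping the hydrogen bookkeeping (complete deltas) apart
from the displayed-DBE bookkeeping makes both unambiguous, and the two
meet in the species-level formula: hydrogens there are
2C + 2k − 2·DBE over k slots plus per-slot bond adjustments, which
reproduces the chain-by-chain result exactly — the conservation
property tested corpus-wide. The plasmenyl double bond stays out of the
printed DBE (the `P-` prefix carries it) and is spent in the formula
arithmetic instead.

Monoisotopic masses use the IUPAC atomic masses embedded as constants;
each positive charge removes one electron mass and m/z divides by
|charge|. Adducts are a data table (token → atom delta and charge,
±1…±4 supported); the clause charge must match the token's, otherwise
the adduct is rejected.

## IUPAC-IUB fatty acyl translation

The multiplier lexicon is generated systematically (unit + tens stem
composition, carbons 1–60, stems stored without the final 'a' so the
morphology of "octadecanoic"/"octadeca-9,12-dienoic"/"eicosatrienoyl"
falls out of the grammar); unsaturation counts run to hexa-. Locants
may appear as standalone prefixes or infixed after the stem. Rules
adopted where the sources only show outcomes:

* locants refer to the parent skeleton's numbering; `nor` prefixes
  delete the named carbons and the remaining carbons renumber
  consecutively from the acid carbon — substituent, ring and suffix
  locants all map through that renumbering;
* `-dioic` acids keep C1 inside the chain and express the far carboxyl
  as a COOH group on the last remaining carbon (chain count =
  skeleton − 1);
* epoxy locant pairs must bridge adjacent carbons and are stored at
  the lower position;
* alkyl substituents of one or two carbons become Me/Et groups, longer
  ones nested chain attachments;
* prostane is a 20-carbon parent with a cyclopentane ring at carbons
  8–12; groups whose renumbered position falls inside the ring span
  print inside the cycle clause;
* `(±)` racemic markers are parsed and dropped; R/S descriptors on
  substituents are kept in the model but the reported level stays at
  full structure, so printed translations carry positions and Z/E
  only — matching how standardized names of such compounds are
  written;
* `-ynoic` names parse syntactically and are rejected as
  `UnsupportedLipid`: triple bonds have no shorthand representation.

## Dialect resolution

`parse_any` tries SHORTHAND2020, LIPIDMAPS, SWISSLIPIDS, HMDB, GOSLIN,
IUPAC-FA in that fixed order; most modern and most specific first, so
legacy grammars never shadow updated-nomenclature names. A grammar
match with unrepresentable chemistry does not stop the search; if
nothing succeeds, the first such semantic error is re-raised, otherwise
`NotParseable` lists the furthest failure offset per dialect. The
legacy grammars deliberately cover the class registry plus each
dialect's separator/prefix conventions, not every database
idiosyncrasy; the class registry (16 classes over the FA, GL, GP, SP,
ST categories) is a data table, so widening coverage is additive.

## The fixture generator

`generate_fixture_names(seed, n, max_depth)` samples random structures
from the model — class, chains with plausible carbon counts (12–24) and
up to three double bonds, 0–2 simple groups, optional ether prefixes,
and nested acyl/alkyl branches firing with probability 0.15 per chain
up to `max_depth` — and prints them at a random hierarchy level.
Sampling structures rather than raw grammar derivations guarantees
semantic validity (positions inside the chain), so every generated name
must parse and round-trip; the corpus tests assert exactly that, plus
formula conservation, on 1,000 names. What the generator does *not*
emulate: real abundance distributions, trivial names, database
formatting noise, adduct clauses, and cycles (which enter via the
IUPAC route); corpus-green therefore demonstrates grammar/printer/
arithmetic self-consistency, not coverage of any real database.

## Problem sizes and numerics

The shipped checks run at desk scale: a 1,000-name corpus for
round-trip and conservation, exhaustive enumeration of all short chain
specifications (≤6 carbons, ≤2 groups, every clause order), and 10,000
mutated names for no-crash fuzzing — a few seconds on one CPU. All
computation is exact integer arithmetic except masses (float sums of
constant atomic masses; test tolerances 5·10⁻⁴ Da). There is no
iterative numerics, no tie-breaking beyond the documented sort orders,
and the only randomness (generator, fuzzer) is seeded.

## Known limitations

Isotope labels, charge states beyond ±4, radical cations, glycan and
sterol-core decorations, trivial-name dictionaries and full database
coverage are out of scope. Names valid in several dialects resolve by
the fixed priority order, which may differ from a source database's
intent.
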