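"""Random generation of valid shorthand names for corpus-scale testing.

Names are produced by sampling random structures from the model (class,
chains, double bonds, functional groups, optional nested acyl/alkyl
branches) and printing them at a randomly chosen hierarchy level with
the canonical printer.  Sampling from the model rather than from raw
grammar derivations guarantees semantic validity (group and double-bond
positions inside the chain), so every generated name must parse and
round-trip — which is exactly what the corpus tests assert.

Branch recursion fires with probability 0.15 per chain and is bounded
by ``max_depth``, keeping derivations finite and names realistic.
"""

from __future__ import annotations

import random

from .model import BondType, Chain, FunctionalGroup, Lipid, LipidLevel
from .normalize import print_name
from .registry import HEADGROUPS, make_group
from .dialects._common import ACYL_BRANCH_DELTA, ALKYL_BRANCH_DELTA

_CLASSES = tuple(HEADGROUPS)
_SIMPLE_GROUPS = ("OH", "oxo", "Me", "OOH", "Ep")
_LEVELS = (
    (LipidLevel.SPECIES, 0.20),
    (LipidLevel.MOLECULAR_SPECIES, 0.15),
    (LipidLevel.SN_POSITION, 0.15),
    (LipidLevel.STRUCTURE_DEFINED, 0.15),
    (LipidLevel.FULL_STRUCTURE, 0.25),
    (LipidLevel.COMPLETE_STRUCTURE, 0.10),
)
BRANCH_PROBABILITY = 0.15


def _pick_level(rng: random.Random) -> LipidLevel:
    x = rng.random()
    acc = 0.0
    for level, w in _LEVELS:
        acc += w
        if x < acc:
            return level
    return LipidLevel.FULL_STRUCTURE


def _random_chain(rng: random.Random, bond: BondType, sn: int,
                  depth: int) -> Chain:
    carbons = rng.choice(range(12, 25, 2)) + rng.choice((0, 0, 0, 1))
    max_db = min(3, (carbons - 2) // 2)
    n_db = rng.choice((0, 0, 1, 1, 2, max_db))
    chain = Chain(num_carbons=carbons, num_dbe=n_db, bond_type=bond,
                  sn_index=sn)
    positions = rng.sample(range(2, carbons - 1), k=n_db) if n_db else []
    for pos in sorted(positions):
        chain.db_positions[pos] = rng.choice("ZZE")
    used = set(positions)
    for _ in range(rng.choice((0, 0, 0, 1, 1, 2))):
        name = rng.choice(_SIMPLE_GROUPS)
        pos = rng.choice([p for p in range(2, carbons + 1) if p not in used])
        used.add(pos)
        g = make_group(name, position=pos)
        if name == "OH" and rng.random() < 0.5:
            g.stereo = rng.choice("RS")
        chain.functional_groups.append(g)
    if depth > 0 and rng.random() < BRANCH_PROBABILITY:
        pos = rng.choice([p for p in range(2, carbons + 1) if p not in used])
        attachment = _random_chain(rng, BondType.FREE, -1, depth - 1)
        attachment.sn_index = -1
        if rng.random() < 0.5:
            chain.functional_groups.append(FunctionalGroup(
                name="O", position=pos, dbe_contribution=1,
                element_delta=ACYL_BRANCH_DELTA.copy(), attachment=attachment))
        else:
            chain.functional_groups.append(FunctionalGroup(
                name="alkyl", position=pos,
                element_delta=ALKYL_BRANCH_DELTA.copy(), attachment=attachment))
    return chain


def _random_lipid(rng: random.Random, max_depth: int) -> Lipid:
    hg = HEADGROUPS[rng.choice(_CLASSES)]
    chains = []
    for i, bond in enumerate(hg.slot_bonds):
        ch = _random_chain(rng, bond, i + 1, max_depth)
        if bond is BondType.ESTER and i == 0 and rng.random() < 0.10:
            ch.bond_type = rng.choice(
                (BondType.ETHER_PLASMANYL, BondType.ETHER_PLASMENYL))
        chains.append(ch)
    return Lipid(headgroup=hg, chains=chains,
                 level=LipidLevel.COMPLETE_STRUCTURE)


def generate_fixture_names(seed: int, n: int, max_depth: int = 1) -> list[str]:
    """``n`` syntactically and semantically valid shorthand names.

    Reproducible for a fixed seed; ``max_depth`` bounds branch nesting
    (0 = flat names only).
    """
    rng = random.Random(seed)
    out = []
    while len(out) < n:
        lipid = _random_lipid(rng, max_depth)
        level = _pick_level(rng)
        out.append(print_name(lipid, level))
    return out
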