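"""Hierarchical structural model for shorthand lipid names.

The model mirrors the graded certainty of the shorthand nomenclature: a
``Lipid`` carries the single hierarchy level its name encodes, from bare
category membership up to a complete structure with stereochemistry.
Everything the dialect parsers produce and the normalizer consumes lives
here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .elements import ElementCounts


class LipidLevel(enum.IntEnum):
    """Structural-information levels, totally ordered coarse -> fine."""

    CATEGORY = 1
    CLASS = 2
    SPECIES = 3
    MOLECULAR_SPECIES = 4
    SN_POSITION = 5
    STRUCTURE_DEFINED = 6
    FULL_STRUCTURE = 7
    COMPLETE_STRUCTURE = 8


class BondType(enum.Enum):
    """How a chain is attached to the lipid scaffold."""

    ESTER = "ester"
    ETHER_PLASMANYL = "plasmanyl"   # O- alkyl ether
    ETHER_PLASMENYL = "plasmenyl"   # P- vinyl ether (1Z-alkenyl)
    AMIDE = "amide"                 # N-acyl, e.g. on a sphingoid base
    LCB = "lcb"                     # long-chain (sphingoid) base itself
    FREE = "free"                   # unbound, e.g. the chain of FA itself


class Category(enum.Enum):
    """Lipid categories in scope."""

    FA = "FA"   # fatty acyls
    GL = "GL"   # glycerolipids
    GP = "GP"   # glycerophospholipids
    SP = "SP"   # sphingolipids
    ST = "ST"   # sterol lipids


@dataclass
class FunctionalGroup:
    """Named decoration on a chain, optionally position/stereo annotated.

    ``element_delta`` is the complete atom delta the group applies to the
    bare chain, hydrogens included.  ``dbe_contribution`` is what the
    group adds to the displayed double-bond-equivalent tally when the
    name is aggregated to sn-position level or coarser.  ``attachment``
    carries a nested chain for acyl/alkyl branches (the recursive case).
    """

    name: str
    position: int = -1          # 1-based carbon; -1 = unknown
    count: int = 1
    stereo: str = ""            # "R", "S" or ""
    element_delta: ElementCounts = field(default_factory=ElementCounts)
    dbe_contribution: int = 0
    attachment: Optional["Chain"] = None

    def total_delta(self) -> ElementCounts:
        """Atom delta including any nested attachment, times count."""
        delta = self.element_delta
        if self.attachment is not None:
            delta = delta + self.attachment.decorated_elements()
        return delta * self.count

    def total_dbe(self) -> int:
        """Displayed-DBE contribution when aggregated, branch included."""
        dbe = self.dbe_contribution
        if self.attachment is not None:
            dbe += self.attachment.display_dbe()
        return dbe * self.count

    def oxygen_tally(self) -> int:
        return self.total_delta().get("O", 0)


@dataclass
class Cycle:
    """A carbocycle spanning a run of main-chain carbons.

    Ring closure contributes exactly one double-bond equivalent, on top
    of any double bonds (``cycle_dbe``) inside the ring.  Functional
    groups positioned within [start, end] print inside the cycle clause.
    """

    start_position: int
    end_position: int
    cycle_carbons: int
    cycle_dbe: int = 0
    internal_groups: list[FunctionalGroup] = field(default_factory=list)

    def total_dbe(self) -> int:
        return 1 + self.cycle_dbe + sum(g.total_dbe() for g in self.internal_groups)

    def total_delta(self) -> ElementCounts:
        out = ElementCounts()
        for g in self.internal_groups:
            out = out + g.total_delta()
        return out


@dataclass
class Chain:
    """A fatty acyl/alkyl/sphingoid moiety.

    ``num_dbe`` counts carbon-carbon double bonds only; carbonyls implied
    by the bond type or carried by functional groups are tracked
    separately.  ``agg_oxygens`` holds the trailing ";O<n>" oxygen tally
    once functional groups have been folded away at sn-position level or
    coarser.
    """

    num_carbons: int
    num_dbe: int = 0
    db_positions: dict[int, str] = field(default_factory=dict)  # pos -> "Z"/"E"/""
    bond_type: BondType = BondType.ESTER
    functional_groups: list[FunctionalGroup] = field(default_factory=list)
    cycles: list[Cycle] = field(default_factory=list)
    sn_index: int = -1
    agg_oxygens: int = 0

    @property
    def is_empty(self) -> bool:
        """A 0:0 placeholder marking an unoccupied sn slot."""
        return self.num_carbons == 0 and not self.functional_groups

    def display_dbe(self) -> int:
        """DBE as shown at aggregated levels: C=C plus group/ring terms."""
        dbe = self.num_dbe
        if self.bond_type is BondType.ETHER_PLASMENYL:
            dbe += 1
        dbe += sum(g.total_dbe() for g in self.functional_groups)
        dbe += sum(c.total_dbe() for c in self.cycles)
        return dbe

    def oxygen_tally(self) -> int:
        """Oxygens added by functional groups (nested included) + tally."""
        return (
            sum(g.oxygen_tally() for g in self.functional_groups)
            + sum(c.total_delta().get("O", 0) for c in self.cycles)
            + self.agg_oxygens
        )

    def total_carbons(self) -> int:
        """Carbons including branch attachments and carbon-adding groups."""
        c = self.num_carbons
        for g in self.functional_groups:
            c += g.total_delta().get("C", 0)
        for cy in self.cycles:
            c += cy.total_delta().get("C", 0)
        return c

    def decorated_elements(self) -> ElementCounts:
        """Atoms of the bare hydrocarbon chain plus all decorations.

        This is the *attachment* form used when the chain hangs off
        another chain as a branch: the bond-type adjustment and the loss
        of water on binding are applied by the owner (see chemistry
        module), not here.  The bare chain contributes C(n)H(2n+2) minus
        2 H per C=C bond and per ring closure/ring double bond.
        """
        if self.num_carbons == 0:
            return ElementCounts()
        h = 2 * self.num_carbons + 2 - 2 * self.num_dbe
        for cy in self.cycles:
            h -= 2 * (1 + cy.cycle_dbe)
        out = ElementCounts({"C": self.num_carbons, "H": h})
        for g in self.functional_groups:
            out = out + g.total_delta()
        for cy in self.cycles:
            out = out + cy.total_delta()
        if self.agg_oxygens:
            out = out + ElementCounts({"O": self.agg_oxygens})
        return out

    def all_groups(self) -> list[FunctionalGroup]:
        """Own functional groups plus those inside cycles."""
        out = list(self.functional_groups)
        for cy in self.cycles:
            out.extend(cy.internal_groups)
        return out


@dataclass(frozen=True)
class Headgroup:
    """Lipid class identity plus its elemental scaffold.

    ``element_template`` is the composition of the class scaffold alone
    (glycerol + phospho-head for GP classes, ethanolamine for NAE, ...);
    chain compositions and the water lost on each ester/ether/amide bond
    are added separately.  ``slot_bonds`` lists the bond type of each
    chain slot in sn order and fixes ``max_chains``.
    """

    class_name: str
    category: Category
    element_template: ElementCounts
    slot_bonds: tuple[BondType, ...]

    @property
    def max_chains(self) -> int:
        return len(self.slot_bonds)


@dataclass
class AggregatedInfo:
    """Species-level totals: the whole ';O3'-style summary."""

    total_carbons: int
    total_dbe: int
    total_oxygens: int


@dataclass
class Lipid:
    """Parse product and normalization subject."""

    headgroup: Headgroup
    chains: list[Chain] = field(default_factory=list)
    level: LipidLevel = LipidLevel.SPECIES
    aggregated_info: Optional[AggregatedInfo] = None
    # bond type of each occupied chain slot, used for species-level
    # formula arithmetic once the chains themselves are gone
    species_bonds: tuple[BondType, ...] = ()

    def validate(self) -> None:
        from .errors import ContractViolation

        if len(self.chains) > self.headgroup.max_chains:
            raise ContractViolation(
                f"{self.headgroup.class_name} admits at most "
                f"{self.headgroup.max_chains} chains, got {len(self.chains)}"
            )
        for ch in self.chains:
            if len(ch.db_positions) > ch.num_dbe:
                raise ContractViolation(
                    f"chain {ch.num_carbons}:{ch.num_dbe} lists "
                    f"{len(ch.db_positions)} double-bond positions"
                )
            for pos in ch.db_positions:
                if not 1 <= pos < ch.num_carbons:
                    raise ContractViolation(
                        f"double-bond position {pos} outside chain of "
                        f"{ch.num_carbons} carbons"
                    )
            for g in ch.all_groups():
                if g.position != -1 and g.attachment is None and g.position > ch.num_carbons:
                    raise ContractViolation(
                        f"group {g.name}@{g.position} beyond chain of "
                        f"{ch.num_carbons} carbons"
                    )


@dataclass(frozen=True)
class Adduct:
    """Ion adduct clause, e.g. [M+H]1+."""

    name: str                   # "+H", "-H", "+NH4", ...
    element_delta: ElementCounts
    charge: int


@dataclass
class LipidAdduct:
    """A parsed name: structure, optional adduct, and its provenance."""

    lipid: Lipid
    adduct: Optional[Adduct] = None
    source_dialect: str = ""
    original_name: str = ""
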