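"""Combinatorial reaction network of the PGHS-1 (COX-1) catalytic cycle.

PGHS-1 is modelled as a set of enzyme microstates defined by the composition
of its catalytic domain: the redox state of the heme prosthetic group (POX
site), the state of the Tyr385 residue, and the occupancy of the fatty-acid
(COX) binding site.  The 3 x 2 x 4 compositions give 24 catalytic states
(E1..E24); three COX-dead states (D1..D3, one per heme state) retain
peroxidase activity only, and a single fully-inactive species (FIE) absorbs
all peroxidase self-inactivation routes.

Reactions are not listed by hand.  Fourteen composition-driven templates
(G1..G11 for catalysis, S1..S3 for self-inactivation) are applied to every
species whose composition matches the template predicate, which closes the
network generatively.  Rate constants come from a unified 18-parameter set;
reactions of the same template share a constant, with occupancy-conditional
selection for tyrosyl-radical reduction (k5 vs k10) and intramolecular
electron transfer (k9 vs k11).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
from lxml import etree

__all__ = [
    "HemeState",
    "TyrState",
    "CoxSiteState",
    "SpeciesKind",
    "Profile",
    "NetworkPolicy",
    "EnzymeSpecies",
    "ParameterSet",
    "ReactionTemplate",
    "ReactionInstance",
    "NetworkModel",
    "NetworkDiagnostics",
    "NetworkError",
    "METABOLITES",
    "DAMAGE_SINK",
    "enumerate_species",
    "instantiate_reactions",
    "build_network",
    "validate_network",
    "export_network",
    "import_network_json",
]

# --------------------------------------------------------------------------
# Component state spaces (Table-1 style composition of the catalytic domain)
# --------------------------------------------------------------------------


class HemeState(enum.Enum):
    """Redox state of the heme prosthetic group in the POX site."""

    FE3_PP = "Fe(III),PP"
    FE4_PPRAD = "Fe(IV),PP*+"
    FE4_PP = "Fe(IV),PP"

    @property
    def radical_bearing(self) -> bool:
        return self is HemeState.FE4_PPRAD


class TyrState(enum.Enum):
    """State of the Tyr385 residue in the COX site."""

    TYR = "Tyr"
    TYR_RAD = "Tyr*"


class CoxSiteState(enum.Enum):
    """Occupancy of the arachidonate (COX) binding site."""

    EMPTY = "empty"
    AA_BOUND = "AA"
    AA_RAD = "AA*"
    PGG2_RAD = "PGG2*"


#: COX-site occupancies that carry one arachidonate backbone.
_ARACHIDONATE_OCCUPANCY = frozenset(
    {CoxSiteState.AA_BOUND, CoxSiteState.AA_RAD, CoxSiteState.PGG2_RAD}
)


class SpeciesKind(enum.Enum):
    CATALYTIC = "catalytic"
    COX_DEAD = "cox_dead"
    FIE = "fie"


class Profile(enum.Enum):
    """Cosubstrate/peroxide profile selecting the POX constants (k5..k8)."""

    PHENOL_PGG2 = "phenol_pgg2"
    ADRENALINE_H2O2 = "adrenaline_h2o2"


class NetworkPolicy(enum.Enum):
    """COMPOSITION_COMPLETE applies every template to every matching species;
    PAPER_ENUMERATED retains only reactions with a published reaction number."""

    COMPOSITION_COMPLETE = "composition_complete"
    PAPER_ENUMERATED = "paper_enumerated"


#: Free metabolite pools, in canonical order.
METABOLITES: tuple[str, ...] = ("AA", "O2", "RC", "OC", "PGG2", "PGH2")

#: Pool receiving arachidonate moieties discarded on enzyme inactivation.
DAMAGE_SINK = "damage_sink"


@dataclass(frozen=True)
class EnzymeSpecies:
    """One enzyme microstate (catalytic composition, COX-dead or FIE)."""

    kind: SpeciesKind
    label: str
    heme: HemeState | None = None
    tyr: TyrState | None = None
    cox_site: CoxSiteState | None = None

    def __post_init__(self) -> None:
        if self.kind is SpeciesKind.CATALYTIC:
            if None in (self.heme, self.tyr, self.cox_site):
                raise ValueError("catalytic species need full composition")
        elif self.kind is SpeciesKind.COX_DEAD:
            if self.heme is None or self.tyr is not None or self.cox_site is not None:
                raise ValueError("COX-dead species carry only a heme state")
        else:  # FIE
            if (self.heme, self.tyr, self.cox_site) != (None, None, None):
                raise ValueError("FIE carries no composition")

    @property
    def bound_arachidonate(self) -> bool:
        return self.cox_site in _ARACHIDONATE_OCCUPANCY


# Canonical labels, E1..E24.  Provenance for each assignment is recorded in
# docs/methods.md; dynamics depend only on composition, labels are bookkeeping.
_CATALYTIC_LABELS: dict[tuple[HemeState, TyrState, CoxSiteState], str] = {
    (HemeState.FE3_PP, TyrState.TYR, CoxSiteState.EMPTY): "E1",
    (HemeState.FE3_PP, TyrState.TYR, CoxSiteState.AA_BOUND): "E14",
    (HemeState.FE3_PP, TyrState.TYR, CoxSiteState.AA_RAD): "E16",
    (HemeState.FE3_PP, TyrState.TYR, CoxSiteState.PGG2_RAD): "E12",
    (HemeState.FE3_PP, TyrState.TYR_RAD, CoxSiteState.EMPTY): "E15",
    (HemeState.FE3_PP, TyrState.TYR_RAD, CoxSiteState.AA_BOUND): "E20",
    (HemeState.FE3_PP, TyrState.TYR_RAD, CoxSiteState.AA_RAD): "E18",
    (HemeState.FE3_PP, TyrState.TYR_RAD, CoxSiteState.PGG2_RAD): "E24",
    (HemeState.FE4_PPRAD, TyrState.TYR, CoxSiteState.EMPTY): "E2",
    (HemeState.FE4_PPRAD, TyrState.TYR, CoxSiteState.AA_BOUND): "E10",
    (HemeState.FE4_PPRAD, TyrState.TYR, CoxSiteState.AA_RAD): "E21",
    (HemeState.FE4_PPRAD, TyrState.TYR, CoxSiteState.PGG2_RAD): "E7",
    (HemeState.FE4_PPRAD, TyrState.TYR_RAD, CoxSiteState.EMPTY): "E11",
    (HemeState.FE4_PPRAD, TyrState.TYR_RAD, CoxSiteState.AA_BOUND): "E19",
    (HemeState.FE4_PPRAD, TyrState.TYR_RAD, CoxSiteState.AA_RAD): "E22",
    (HemeState.FE4_PPRAD, TyrState.TYR_RAD, CoxSiteState.PGG2_RAD): "E23",
    (HemeState.FE4_PP, TyrState.TYR, CoxSiteState.EMPTY): "E3",
    (HemeState.FE4_PP, TyrState.TYR, CoxSiteState.AA_BOUND): "E6",
    (HemeState.FE4_PP, TyrState.TYR, CoxSiteState.AA_RAD): "E13",
    (HemeState.FE4_PP, TyrState.TYR, CoxSiteState.PGG2_RAD): "E8",
    (HemeState.FE4_PP, TyrState.TYR_RAD, CoxSiteState.EMPTY): "E5",
    (HemeState.FE4_PP, TyrState.TYR_RAD, CoxSiteState.AA_BOUND): "E9",
    (HemeState.FE4_PP, TyrState.TYR_RAD, CoxSiteState.AA_RAD): "E17",
    (HemeState.FE4_PP, TyrState.TYR_RAD, CoxSiteState.PGG2_RAD): "E4",
}

_DEAD_LABELS: dict[HemeState, str] = {
    HemeState.FE3_PP: "D1",
    HemeState.FE4_PPRAD: "D2",
    HemeState.FE4_PP: "D3",
}

FIE_LABEL = "FIE"


def _label_sort_key(label: str) -> tuple[int, int]:
    if label.startswith("E"):
        return (0, int(label[1:]))
    if label.startswith("D"):
        return (1, int(label[1:]))
    return (2, 0)


# --------------------------------------------------------------------------
# Parameters (unified fitted set; two POX-substrate profiles)
# --------------------------------------------------------------------------

_RATE_UNITS: dict[str, str] = {
    "k1": "1/(uM*s)", "Kd1": "uM", "k2": "1/s", "k3": "1/(uM^2*s)",
    "k4": "1/s", "k5": "1/(uM*s)", "k6": "1/(uM*s)", "k7": "1/(uM*s)",
    "k8": "1/(uM*s)", "k9": "1/s", "k10": "1/(uM*s)", "k11": "1/s",
    "k12": "1/(uM*s)", "Kd12": "uM", "k13": "1/s", "kin": "1/s",
    "kin1": "1/s", "kin2": "1/s",
}

PARAMETER_NAMES: tuple[str, ...] = tuple(_RATE_UNITS)

#: POX-block overrides when the cosubstrate is adrenaline and the peroxide H2O2.
_ADRENALINE_POX_BLOCK = {"k5": 0.06, "k6": 0.001, "k7": 0.001, "k8": 0.001}


@dataclass(frozen=True)
class ParameterSet:
    """The 18 fitted rate constants of the unified PGHS-1 parameter set.

    Defaults are the phenol/PGG2 values; ``Profile.ADRENALINE_H2O2`` swaps the
    POX subset (k5, k6, k7, k8) for the adrenaline/H2O2 block.  Kd values are
    dissociation constants, so every binding reaction unbinds at kon * Kd.
    """

    k1: float = 690.0      # AA on-rate to Tyr*-bearing empty sites, 1/(uM s)
    Kd1: float = 0.1       # AA dissociation constant for k1 bindings, uM
    k2: float = 2690.0     # H abstraction Tyr* + AA -> Tyr + AA*, 1/s
    k3: float = 173.0      # oxygenation AA* + 2 O2 -> PGG2*, 1/(uM^2 s)
    k4: float = 13.0       # PGG2 release with Tyr* regeneration, 1/s
    k5: float = 0.18       # Tyr* reduction by RC (empty/PGG2* site), 1/(uM s)
    k6: float = 0.58       # ferryl Fe(IV)PP reduction by RC, 1/(uM s)
    k7: float = 7.1        # peroxidase step Fe(III) + PGG2, 1/(uM s)
    k8: float = 0.001      # PP*+ reduction by RC, 1/(uM s)
    k9: float = 310.0      # intramolecular e- transfer, empty COX site, 1/s
    k10: float = 0.1       # Tyr* reduction by RC, AA-occupied site, 1/(uM s)
    k11: float = 1.1       # intramolecular e- transfer, occupied site, 1/s
    k12: float = 690.0     # AA on-rate to ground-Tyr empty sites, 1/(uM s)
    Kd12: float = 0.6      # AA dissociation constant for k12 bindings, uM
    k13: float = 18.8      # TC-route H abstraction by PP*+, 1/s
    kin: float = 0.72      # COX-site inactivation (to COX-dead), 1/s
    kin1: float = 0.6      # POX inactivation from PP*+ states (to FIE), 1/s
    kin2: float = 2.5      # POX inactivation from ferryl/Tyr* states, 1/s
    profile: Profile = Profile.PHENOL_PGG2

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"negative rate constant {name}")

    @classmethod
    def default(cls, profile: Profile = Profile.PHENOL_PGG2) -> "ParameterSet":
        if profile is Profile.ADRENALINE_H2O2:
            return cls(profile=profile, **_ADRENALINE_POX_BLOCK)
        return cls(profile=profile)

    def with_values(self, **overrides: float) -> "ParameterSet":
        unknown = set(overrides) - set(PARAMETER_NAMES)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        return replace(self, **overrides)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}

    @staticmethod
    def units(name: str) -> str:
        return _RATE_UNITS[name]


# --------------------------------------------------------------------------
# Reaction templates
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionTemplate:
    """A composition-driven reaction rule.

    ``applies`` filters species, ``transform`` maps reactant composition to
    product composition, ``rate`` selects the forward constant (occupancy
    conditional where needed), ``metabolites`` are net pool deltas and
    ``consumed`` the mass-action factors beyond the enzyme itself.
    """

    id: str
    description: str
    applies: Callable[[EnzymeSpecies], bool]
    transform: Callable[[EnzymeSpecies], tuple]
    rate: Callable[[ParameterSet, EnzymeSpecies], float]
    metabolites: Callable[[EnzymeSpecies], dict[str, int]]
    consumed: tuple[tuple[str, int], ...] = ()
    reversible: bool = False
    reverse_rate: Callable[[ParameterSet, EnzymeSpecies], float] | None = None


def _cat(s: EnzymeSpecies) -> bool:
    return s.kind is SpeciesKind.CATALYTIC


def _cat_or_dead(s: EnzymeSpecies) -> bool:
    return s.kind in (SpeciesKind.CATALYTIC, SpeciesKind.COX_DEAD)


def _same(s: EnzymeSpecies, **changes) -> tuple:
    comp = {"kind": s.kind, "heme": s.heme, "tyr": s.tyr, "cox_site": s.cox_site}
    comp.update(changes)
    return (comp["kind"], comp["heme"], comp["tyr"], comp["cox_site"])


def _no_mets(_s: EnzymeSpecies) -> dict[str, int]:
    return {}


def _sink_mets(s: EnzymeSpecies) -> dict[str, int]:
    # Bound arachidonate backbone is discarded to the damage sink.
    return {DAMAGE_SINK: 1} if s.bound_arachidonate else {}


_S2_SOURCES = frozenset({"E5", "E9", "E15", "E20"})

TEMPLATES: tuple[ReactionTemplate, ...] = (
    ReactionTemplate(
        id="G1",
        description="AA binding to tyrosyl-radical states with an empty COX site",
        applies=lambda s: _cat(s) and s.tyr is TyrState.TYR_RAD
        and s.cox_site is CoxSiteState.EMPTY,
        transform=lambda s: _same(s, cox_site=CoxSiteState.AA_BOUND),
        rate=lambda p, s: p.k1,
        metabolites=lambda s: {"AA": -1},
        consumed=(("AA", 1),),
        reversible=True,
        reverse_rate=lambda p, s: p.k1 * p.Kd1,
    ),
    ReactionTemplate(
        id="G2",
        description="AA binding to ground-Tyr states with an empty COX site",
        applies=lambda s: _cat(s) and s.tyr is TyrState.TYR
        and s.cox_site is CoxSiteState.EMPTY,
        transform=lambda s: _same(s, cox_site=CoxSiteState.AA_BOUND),
        rate=lambda p, s: p.k12,
        metabolites=lambda s: {"AA": -1},
        consumed=(("AA", 1),),
        reversible=True,
        reverse_rate=lambda p, s: p.k12 * p.Kd12,
    ),
    ReactionTemplate(
        id="G3",
        description="H abstraction from bound AA by the Tyr385 radical",
        applies=lambda s: _cat(s) and s.tyr is TyrState.TYR_RAD
        and s.cox_site is CoxSiteState.AA_BOUND,
        transform=lambda s: _same(s, tyr=TyrState.TYR, cox_site=CoxSiteState.AA_RAD),
        rate=lambda p, s: p.k2,
        metabolites=_no_mets,
    ),
    ReactionTemplate(
        id="G4",
        description="oxygenation of the arachidonyl radical by two O2",
        applies=lambda s: _cat(s) and s.cox_site is CoxSiteState.AA_RAD,
        transform=lambda s: _same(s, cox_site=CoxSiteState.PGG2_RAD),
        rate=lambda p, s: p.k3,
        metabolites=lambda s: {"O2": -2},
        consumed=(("O2", 2),),
    ),
    ReactionTemplate(
        id="G5",
        description="PGG2 release regenerating the Tyr385 radical",
        applies=lambda s: _cat(s) and s.tyr is TyrState.TYR
        and s.cox_site is CoxSiteState.PGG2_RAD,
        transform=lambda s: _same(
            s, tyr=TyrState.TYR_RAD, cox_site=CoxSiteState.EMPTY
        ),
        rate=lambda p, s: p.k4,
        metabolites=lambda s: {"PGG2": 1},
    ),
    ReactionTemplate(
        id="G6",
        description="peroxidase step: Fe(III) + PGG2 -> Fe(IV),PP*+ + PGH2",
        applies=lambda s: _cat_or_dead(s) and s.heme is HemeState.FE3_PP,
        transform=lambda s: _same(s, heme=HemeState.FE4_PPRAD),
        rate=lambda p, s: p.k7,
        metabolites=lambda s: {"PGG2": -1, "PGH2": 1},
        consumed=(("PGG2", 1),),
    ),
    ReactionTemplate(
        id="G7",
        description="reduction of the protoporphyrin radical cation by RC",
        applies=lambda s: _cat_or_dead(s) and s.heme is HemeState.FE4_PPRAD,
        transform=lambda s: _same(s, heme=HemeState.FE4_PP),
        rate=lambda p, s: p.k8,
        metabolites=lambda s: {"RC": -1, "OC": 1},
        consumed=(("RC", 1),),
    ),
    ReactionTemplate(
        id="G8",
        description="reduction of the ferryl heme Fe(IV),PP by RC",
        applies=lambda s: _cat_or_dead(s) and s.heme is HemeState.FE4_PP,
        transform=lambda s: _same(s, heme=HemeState.FE3_PP),
        rate=lambda p, s: p.k6,
        metabolites=lambda s: {"RC": -1, "OC": 1},
        consumed=(("RC", 1),),
    ),
    ReactionTemplate(
        id="G9",
        description="reduction of the Tyr385 radical by RC",
        applies=lambda s: _cat(s) and s.tyr is TyrState.TYR_RAD,
        transform=lambda s: _same(s, tyr=TyrState.TYR),
        rate=lambda p, s: p.k5
        if s.cox_site in (CoxSiteState.EMPTY, CoxSiteState.PGG2_RAD)
        else p.k10,
        metabolites=lambda s: {"RC": -1, "OC": 1},
        consumed=(("RC", 1),),
    ),
    ReactionTemplate(
        id="G10",
        # k11 belongs to the arachidonate-occupied transfers (the AA-bearing
        # peroxidase cycle); a PGG2 radical in the COX site does not hinder
        # the transfer, in line with the k5-vs-k10 occupancy rule for RC.
        description="intramolecular electron transfer PP*+ + Tyr -> PP + Tyr*",
        applies=lambda s: _cat(s) and s.heme is HemeState.FE4_PPRAD
        and s.tyr is TyrState.TYR,
        transform=lambda s: _same(s, heme=HemeState.FE4_PP, tyr=TyrState.TYR_RAD),
        rate=lambda p, s: p.k9
        if s.cox_site in (CoxSiteState.EMPTY, CoxSiteState.PGG2_RAD)
        else p.k11,
        metabolites=_no_mets,
    ),
    ReactionTemplate(
        id="G11",
        description="TC-route H abstraction from bound AA by PP*+",
        applies=lambda s: _cat(s) and s.heme is HemeState.FE4_PPRAD
        and s.tyr is TyrState.TYR and s.cox_site is CoxSiteState.AA_BOUND,
        transform=lambda s: _same(s, heme=HemeState.FE4_PP, cox_site=CoxSiteState.AA_RAD),
        rate=lambda p, s: p.k13,
        metabolites=_no_mets,
    ),
    ReactionTemplate(
        id="S1",
        description="POX self-inactivation from PP*+-bearing species",
        applies=lambda s: _cat_or_dead(s) and s.heme is HemeState.FE4_PPRAD,
        transform=lambda s: (SpeciesKind.FIE, None, None, None),
        rate=lambda p, s: p.kin1,
        metabolites=_sink_mets,
    ),
    ReactionTemplate(
        id="S2",
        description="POX self-inactivation from ferryl/tyrosyl intermediates",
        applies=lambda s: _cat(s) and s.label in _S2_SOURCES,
        transform=lambda s: (SpeciesKind.FIE, None, None, None),
        rate=lambda p, s: p.kin2,
        metabolites=_sink_mets,
    ),
    ReactionTemplate(
        id="S3",
        # sources: every Tyr*-bearing state with an empty or AA-occupied COX
        # site, plus the two-radical states on the ferryl heme (Tyr* with AA*
        # or PGG2* and Fe(IV),PP) - the eight documented COX-death routes.
        description="COX-site inactivation from tyrosyl-radical states",
        applies=lambda s: _cat(s) and s.tyr is TyrState.TYR_RAD
        and (
            s.cox_site in (CoxSiteState.EMPTY, CoxSiteState.AA_BOUND)
            or s.heme is HemeState.FE4_PP
        ),
        transform=lambda s: (SpeciesKind.COX_DEAD, s.heme, None, None),
        rate=lambda p, s: p.kin,
        metabolites=_sink_mets,
    ),
)

TEMPLATE_IDS: tuple[str, ...] = tuple(t.id for t in TEMPLATES)

# Reaction numbers used in the source literature, where the text names one.
PAPER_REACTION_NUMBERS: dict[tuple[str, str], int] = {
    ("G1", "E5"): 1, ("G1", "E15"): 5, ("G1", "E11"): 47,
    ("G2", "E1"): 31, ("G2", "E2"): 32, ("G2", "E3"): 30,
    ("G3", "E9"): 2, ("G3", "E20"): 6, ("G3", "E19"): 64,
    ("G4", "E13"): 3, ("G4", "E16"): 7, ("G4", "E21"): 33,
    ("G5", "E8"): 4, ("G5", "E12"): 8, ("G5", "E7"): 52,
    ("G6", "E1"): 11, ("G6", "E14"): 16, ("G6", "E16"): 20,
    ("G6", "E12"): 23, ("G6", "D1"): 25,
    ("G7", "E2"): 12, ("G7", "D2"): 26,
    ("G8", "E3"): 10, ("G8", "E5"): 19, ("G8", "E8"): 22,
    ("G8", "E9"): 28, ("G8", "E13"): 29, ("G8", "D3"): 27,
    ("G9", "E5"): 9, ("G9", "E4"): 49, ("G9", "E15"): 50,
    ("G9", "E9"): 14, ("G9", "E20"): 51,
    ("G10", "E2"): 13, ("G10", "E10"): 18,
    ("G11", "E10"): 56,
    ("S1", "E2"): 38, ("S1", "E7"): 39, ("S1", "E11"): 40,
    ("S1", "E19"): 41, ("S1", "E21"): 53, ("S1", "E23"): 67, ("S1", "D2"): 42,
    ("S2", "E5"): 43, ("S2", "E9"): 44, ("S2", "E15"): 45, ("S2", "E20"): 46,
    ("S3", "E17"): 36, ("S3", "E4"): 37, ("S3", "E5"): 58, ("S3", "E9"): 59,
    ("S3", "E11"): 60, ("S3", "E15"): 61, ("S3", "E19"): 62, ("S3", "E20"): 68,
}


@dataclass(frozen=True)
class ReactionInstance:
    """One instantiated mass-action reaction between enzyme microstates."""

    index: int
    template_id: str
    reactant: str
    product: str
    metabolites: Mapping[str, int]
    kf: float
    kr: float = 0.0
    paper_reaction: int | None = None
    consumed: tuple[tuple[str, int], ...] = ()

    @property
    def reversible(self) -> bool:
        return self.kr > 0.0

    @property
    def order(self) -> int:
        return 1 + sum(n for _m, n in self.consumed)


class NetworkError(ValueError):
    """Structural violation of the network contracts."""


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def enumerate_species(
    policy: NetworkPolicy = NetworkPolicy.COMPOSITION_COMPLETE,
) -> list[EnzymeSpecies]:
    """Enumerate all 28 enzyme species (24 catalytic + 3 COX-dead + FIE).

    The species set does not depend on the policy (the policy restricts the
    reaction set only); it is accepted for interface symmetry.
    """
    if not isinstance(policy, NetworkPolicy):
        raise NetworkError(f"unknown policy {policy!r}")
    species = [
        EnzymeSpecies(SpeciesKind.CATALYTIC, label, heme, tyr, site)
        for (heme, tyr, site), label in _CATALYTIC_LABELS.items()
    ]
    species.extend(
        EnzymeSpecies(SpeciesKind.COX_DEAD, label, heme)
        for heme, label in _DEAD_LABELS.items()
    )
    species.append(EnzymeSpecies(SpeciesKind.FIE, FIE_LABEL))
    species.sort(key=lambda s: _label_sort_key(s.label))
    return species


def _label_for(kind: SpeciesKind, heme, tyr, cox_site) -> str:
    if kind is SpeciesKind.CATALYTIC:
        return _CATALYTIC_LABELS[(heme, tyr, cox_site)]
    if kind is SpeciesKind.COX_DEAD:
        return _DEAD_LABELS[heme]
    return FIE_LABEL


def instantiate_reactions(
    species: Sequence[EnzymeSpecies],
    params: ParameterSet,
    policy: NetworkPolicy = NetworkPolicy.COMPOSITION_COMPLETE,
) -> list[ReactionInstance]:
    """Apply every template to every matching species.

    The result is independent of the input ordering of ``species`` (reactions
    are generated in canonical label order).  Reactions whose selected forward
    rate constant is exactly zero are omitted: a zero constant switches the
    route off, structurally as well as numerically.
    """
    if not isinstance(policy, NetworkPolicy):
        raise NetworkError(f"unknown policy {policy!r}")
    if not isinstance(params, ParameterSet):
        raise NetworkError("params must be a ParameterSet")

    ordered = sorted(species, key=lambda s: _label_sort_key(s.label))
    reactions: list[ReactionInstance] = []
    for template in TEMPLATES:
        for sp in ordered:
            if not template.applies(sp):
                continue
            number = PAPER_REACTION_NUMBERS.get((template.id, sp.label))
            if policy is NetworkPolicy.PAPER_ENUMERATED and number is None:
                continue
            kf = template.rate(params, sp)
            if kf == 0.0:
                continue
            kr = template.reverse_rate(params, sp) if template.reversible else 0.0
            product_label = _label_for(*template.transform(sp))
            reactions.append(
                ReactionInstance(
                    index=len(reactions),
                    template_id=template.id,
                    reactant=sp.label,
                    product=product_label,
                    metabolites=dict(template.metabolites(sp)),
                    kf=kf,
                    kr=kr,
                    paper_reaction=number,
                    consumed=template.consumed,
                )
            )
    return reactions


@dataclass(frozen=True)
class NetworkModel:
    """Species list, reaction list and the parameter set behind them."""

    species: tuple[EnzymeSpecies, ...]
    reactions: tuple[ReactionInstance, ...]
    params: ParameterSet
    policy: NetworkPolicy

    def species_labels(self) -> list[str]:
        return [s.label for s in self.species]

    def species_by_label(self, label: str) -> EnzymeSpecies:
        for s in self.species:
            if s.label == label:
                return s
        raise KeyError(label)

    def reaction_by_paper_number(self, number: int) -> ReactionInstance:
        for r in self.reactions:
            if r.paper_reaction == number:
                return r
        raise KeyError(f"no reaction with published number {number}")

    def with_params(self, params: ParameterSet) -> "NetworkModel":
        return build_network(params=params, policy=self.policy)

    def subnetwork(self, paper_numbers: Iterable[int]) -> "NetworkModel":
        """Restrict to reactions with the given published numbers (reduced
        models used for oracle checks)."""
        keep = set(paper_numbers)
        reactions = tuple(
            replace(r, index=i)
            for i, r in enumerate(
                r for r in self.reactions if r.paper_reaction in keep
            )
        )
        missing = keep - {r.paper_reaction for r in reactions}
        if missing:
            raise KeyError(f"unknown reaction numbers {sorted(missing)}")
        return NetworkModel(self.species, reactions, self.params, self.policy)


def build_network(
    params: ParameterSet | None = None,
    policy: NetworkPolicy = NetworkPolicy.COMPOSITION_COMPLETE,
) -> NetworkModel:
    """Build the full enzyme network with the given (default: fitted) constants."""
    params = params or ParameterSet.default()
    species = enumerate_species(policy)
    reactions = instantiate_reactions(species, params, policy)
    return NetworkModel(tuple(species), tuple(reactions), params, policy)


@dataclass
class NetworkDiagnostics:
    enzyme_closure: bool
    fie_absorbing: bool
    unreachable_from_e1: list[str]
    no_outgoing: list[str]

    @property
    def ok(self) -> bool:
        return (
            self.enzyme_closure
            and self.fie_absorbing
            and not self.unreachable_from_e1
        )


def validate_network(model: NetworkModel) -> NetworkDiagnostics:
    """Check structural contracts of the network.

    Hard errors (exceptions): a reaction not mapping exactly one enzyme
    species to one enzyme species, or an outgoing reaction from FIE.
    Warnings (reported, not raised): species unreachable from the resting
    state E1, and species without outgoing reactions.
    """
    labels = set(model.species_labels())
    for r in model.reactions:
        if r.reactant not in labels or r.product not in labels:
            raise NetworkError(f"reaction {r.index} does not conserve the enzyme moiety")
        if r.reactant == FIE_LABEL:
            raise NetworkError("FIE must be absorbing")

    graph = nx.DiGraph()
    graph.add_nodes_from(labels)
    for r in model.reactions:
        graph.add_edge(r.reactant, r.product)
        if r.reversible:
            graph.add_edge(r.product, r.reactant)

    reachable = nx.descendants(graph, "E1") | {"E1"}
    unreachable = sorted(labels - reachable, key=_label_sort_key)
    no_out = sorted(
        (lab for lab in labels if graph.out_degree(lab) == 0 and lab != FIE_LABEL),
        key=_label_sort_key,
    )
    return NetworkDiagnostics(
        enzyme_closure=True,
        fie_absorbing=True,
        unreachable_from_e1=unreachable,
        no_outgoing=no_out,
    )


# --------------------------------------------------------------------------
# Serialization: JSON (round-trippable), GraphML, SBML L3V2
# --------------------------------------------------------------------------


def _model_to_dict(model: NetworkModel) -> dict:
    return {
        "policy": model.policy.value,
        "params": {**model.params.as_dict(), "profile": model.params.profile.value},
        "species": [
            {
                "label": s.label,
                "kind": s.kind.value,
                "heme": s.heme.name if s.heme else None,
                "tyr": s.tyr.name if s.tyr else None,
                "cox_site": s.cox_site.name if s.cox_site else None,
            }
            for s in model.species
        ],
        "reactions": [
            {
                "index": r.index,
                "template": r.template_id,
                "reactant": r.reactant,
                "product": r.product,
                "metabolites": dict(r.metabolites),
                "kf": r.kf,
                "kr": r.kr,
                "paper_reaction": r.paper_reaction,
                "consumed": [list(c) for c in r.consumed],
            }
            for r in model.reactions
        ],
    }


def import_network_json(document: str) -> NetworkModel:
    data = json.loads(document)
    params_data = dict(data["params"])
    profile = Profile(params_data.pop("profile"))
    params = ParameterSet(profile=profile, **params_data)
    species = tuple(
        EnzymeSpecies(
            kind=SpeciesKind(s["kind"]),
            label=s["label"],
            heme=HemeState[s["heme"]] if s["heme"] else None,
            tyr=TyrState[s["tyr"]] if s["tyr"] else None,
            cox_site=CoxSiteState[s["cox_site"]] if s["cox_site"] else None,
        )
        for s in data["species"]
    )
    reactions = tuple(
        ReactionInstance(
            index=r["index"],
            template_id=r["template"],
            reactant=r["reactant"],
            product=r["product"],
            metabolites=dict(r["metabolites"]),
            kf=r["kf"],
            kr=r["kr"],
            paper_reaction=r["paper_reaction"],
            consumed=tuple((m, int(n)) for m, n in r["consumed"]),
        )
        for r in data["reactions"]
    )
    return NetworkModel(species, reactions, params, NetworkPolicy(data["policy"]))


def _model_to_graphml(model: NetworkModel) -> str:
    g = nx.DiGraph()
    for s in model.species:
        g.add_node(s.label, kind=s.kind.value)
    for m in METABOLITES:
        g.add_node(m, kind="metabolite")
    for r in model.reactions:
        g.add_edge(r.reactant, r.product, template=r.template_id, kf=r.kf,
                   reaction=r.index)
        for met, delta in r.metabolites.items():
            if met == DAMAGE_SINK:
                continue
            if delta < 0:
                g.add_edge(met, r.reactant, reaction=r.index, stoich=delta)
            else:
                g.add_edge(r.reactant, met, reaction=r.index, stoich=delta)
    return "\n".join(nx.generate_graphml(g))


_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _mathml_product(factors: list[tuple[str, int]], mathml) -> etree._Element:
    terms: list[etree._Element] = []
    for name, power in factors:
        ci = mathml("ci")
        ci.text = f" {name} "
        if power == 1:
            terms.append(ci)
        else:
            ap = mathml("apply")
            ap.append(mathml("power"))
            ap.append(ci)
            cn = mathml("cn")
            cn.set("type", "integer")
            cn.text = f" {power} "
            ap.append(cn)
            terms.append(ap)
    if len(terms) == 1:
        return terms[0]
    ap = mathml("apply")
    ap.append(mathml("times"))
    for t in terms:
        ap.append(t)
    return ap


def _model_to_sbml(model: NetworkModel) -> str:
    """Serialize as SBML Level 3 Version 2 with explicit mass-action laws.

    Concentrations are micromolar, time is seconds; each reaction's kinetic
    law is k * [enzyme] * prod [consumed metabolite]^n, with an explicit
    reverse term for the two reversible binding templates.
    """
    nsmap = {None: _SBML_NS}
    sbml = etree.Element(f"{{{_SBML_NS}}}sbml", nsmap=nsmap)
    sbml.set("level", "3")
    sbml.set("version", "2")
    mdl = etree.SubElement(sbml, f"{{{_SBML_NS}}}model")
    mdl.set("id", "pghs1_cycle_network")
    mdl.set("substanceUnits", "umole")
    mdl.set("timeUnits", "second")
    mdl.set("extentUnits", "umole")

    units = etree.SubElement(mdl, f"{{{_SBML_NS}}}listOfUnitDefinitions")
    for uid, kinds in (
        ("umole", [("mole", 1, -6, 1.0)]),
        ("uM", [("mole", 1, -6, 1.0), ("litre", -1, 0, 1.0)]),
    ):
        ud = etree.SubElement(units, f"{{{_SBML_NS}}}unitDefinition")
        ud.set("id", uid)
        lou = etree.SubElement(ud, f"{{{_SBML_NS}}}listOfUnits")
        for kind, exp, scale, mult in kinds:
            u = etree.SubElement(lou, f"{{{_SBML_NS}}}unit")
            u.set("kind", kind)
            u.set("exponent", str(exp))
            u.set("scale", str(scale))
            u.set("multiplier", str(mult))

    comps = etree.SubElement(mdl, f"{{{_SBML_NS}}}listOfCompartments")
    comp = etree.SubElement(comps, f"{{{_SBML_NS}}}compartment")
    comp.set("id", "cell")
    comp.set("spatialDimensions", "3")
    comp.set("size", "1")
    comp.set("units", "litre")
    comp.set("constant", "true")

    los = etree.SubElement(mdl, f"{{{_SBML_NS}}}listOfSpecies")
    for name in [s.label for s in model.species] + list(METABOLITES) + [DAMAGE_SINK]:
        sp = etree.SubElement(los, f"{{{_SBML_NS}}}species")
        sp.set("id", name)
        sp.set("compartment", "cell")
        sp.set("initialConcentration", "0")
        sp.set("hasOnlySubstanceUnits", "false")
        sp.set("boundaryCondition", "false")
        sp.set("constant", "false")

    lop = etree.SubElement(mdl, f"{{{_SBML_NS}}}listOfParameters")
    for r in model.reactions:
        for suffix, value in (("f", r.kf),) + ((("r", r.kr),) if r.reversible else ()):
            par = etree.SubElement(lop, f"{{{_SBML_NS}}}parameter")
            par.set("id", f"k_{r.index}_{suffix}")
            par.set("value", repr(value))
            par.set("constant", "true")

    lor = etree.SubElement(mdl, f"{{{_SBML_NS}}}listOfReactions")
    mathml = lambda tag: etree.Element(f"{{{_MATHML_NS}}}{tag}")  # noqa: E731
    for r in model.reactions:
        rx = etree.SubElement(lor, f"{{{_SBML_NS}}}reaction")
        rx.set("id", f"r{r.index}_{r.template_id}_{r.reactant}")
        rx.set("reversible", "true" if r.reversible else "false")
        reactants = {r.reactant: 1}
        products = {r.product: 1}
        for met, delta in r.metabolites.items():
            pool = reactants if delta < 0 else products
            pool[met] = pool.get(met, 0) + abs(delta)
        for tag, pool in (("listOfReactants", reactants), ("listOfProducts", products)):
            lo = etree.SubElement(rx, f"{{{_SBML_NS}}}{tag}")
            for name, stoich in pool.items():
                ref = etree.SubElement(lo, f"{{{_SBML_NS}}}speciesReference")
                ref.set("species", name)
                ref.set("stoichiometry", str(stoich))
                ref.set("constant", "true")
        kl = etree.SubElement(rx, f"{{{_SBML_NS}}}kineticLaw")
        math = etree.SubElement(kl, f"{{{_MATHML_NS}}}math")
        fwd_factors = [(f"k_{r.index}_f", 1), (r.reactant, 1)] + [
            (met, n) for met, n in r.consumed
        ]
        fwd = _mathml_product(fwd_factors, mathml)
        if r.reversible:
            rev = _mathml_product([(f"k_{r.index}_r", 1), (r.product, 1)], mathml)
            minus = mathml("apply")
            minus.append(mathml("minus"))
            minus.append(fwd)
            minus.append(rev)
            math.append(minus)
        else:
            math.append(fwd)

    return etree.tostring(
        sbml, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode()


def export_network(model: NetworkModel, format: str) -> str:
    """Serialize the model; ``format`` is one of {"json", "sbml", "graphml"}."""
    fmt = format.lower()
    if fmt == "json":
        return json.dumps(_model_to_dict(model), indent=1, sort_keys=True)
    if fmt == "graphml":
        return _model_to_graphml(model)
    if fmt == "sbml":
        return _model_to_sbml(model)
    raise ValueError(f"unsupported format {format!r}")
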