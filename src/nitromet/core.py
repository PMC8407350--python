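"""Domain types for the core stoichiometric model.

The model is a compartmented metabolic network (cytoplasm ``c``,
periplasm ``p``, extracellular ``e``) whose species carry elemental
formulas and charges so that every internal reaction can be checked for
mass and charge conservation.  The stoichiometric matrix ``S`` (species
rows x reaction columns) is derived on demand.

Units follow the field convention: fluxes in mmol gDW-1 h-1, the
biomass reaction in h-1, biomass composition as percent dry weight and
umol per mg dry weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np

COMPARTMENTS = ("cytoplasm", "periplasm", "extracellular")

#: suffix convention mirroring ModelSEED-style ids (rxn00690_c0 etc.)
COMPARTMENT_SUFFIX = {"cytoplasm": "_c0", "periplasm": "_p0", "extracellular": "_e0"}

ELEMENTS = ("C", "H", "N", "O", "P", "S")


class ModelConstructionError(ValueError):
    """Raised when a model or reaction violates a structural invariant."""


@dataclass(frozen=True)
class Species:
    """A metabolite in one compartment.

    ``formula`` maps element symbol to a non-negative integer count.
    Abstract electron carriers (ferredoxin, cytochrome c) use an empty
    formula and carry redox state in ``charge`` only; that is a *known*
    (zero-atom) formula, not a missing one.
    """

    id: str
    name: str
    compartment: str
    #: element -> count; an *empty* mapping is a declared-abstract species
    #: (zero atoms, e.g. electron-carrier scaffolds), while ``None`` means
    #: the formula is genuinely unknown and balance checks must flag it.
    formula: Optional[Mapping[str, int]] = field(default_factory=dict)
    charge: int = 0
    #: molar mass override (g/mol) for species whose formula is abstract
    #: but which appear in the biomass mass balance (e.g. the ash pool).
    mass: Optional[float] = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelConstructionError(
                f"species {self.id!r}: compartment {self.compartment!r} "
                f"not one of {COMPARTMENTS}"
            )
        for el, n in (self.formula or {}).items():
            if not float(n) == int(n) or n < 0:
                raise ModelConstructionError(
                    f"species {self.id!r}: formula count {el}={n} must be a "
                    "non-negative integer"
                )

    @property
    def molar_mass(self) -> float:
        if self.mass is not None:
            return self.mass
        return sum(ATOMIC_MASS[el] * n for el, n in (self.formula or {}).items())


ATOMIC_MASS = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}


@dataclass
class Reaction:
    """A stoichiometric reaction.

    ``stoichiometry`` maps species id to a signed coefficient
    (negative = consumed).  Bounds are mmol gDW-1 h-1 (h-1 for the
    biomass reaction).
    """

    id: str
    name: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    subsystem: str = ""
    gene_note: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelConstructionError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelConstructionError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        return self.subsystem == "exchange"

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            name=self.name,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            subsystem=self.subsystem,
            gene_note=self.gene_note,
        )


@dataclass
class MetabolicModel:
    """Species + reactions + objective; exposes the S matrix."""

    species: List[Species]
    reactions: List[Reaction]
    objective_id: str
    name: str = "nitromet-core"

    def __post_init__(self) -> None:
        self._index()
        self.validate()

    def _index(self) -> None:
        self._species_by_id = {s.id: s for s in self.species}
        self._reactions_by_id = {r.id: r for r in self.reactions}

    def validate(self) -> None:
        if len(self._species_by_id) != len(self.species):
            seen: set = set()
            dup = [s.id for s in self.species if s.id in seen or seen.add(s.id)]
            raise ModelConstructionError(f"duplicate species ids: {dup}")
        if len(self._reactions_by_id) != len(self.reactions):
            seen = set()
            dup = [r.id for r in self.reactions if r.id in seen or seen.add(r.id)]
            raise ModelConstructionError(f"duplicate reaction ids: {dup}")
        for r in self.reactions:
            for sid in r.stoichiometry:
                if sid not in self._species_by_id:
                    raise ModelConstructionError(
                        f"reaction {r.id!r} references unknown species {sid!r}"
                    )
            if r.is_exchange:
                if len(r.stoichiometry) != 1:
                    raise ModelConstructionError(
                        f"exchange reaction {r.id!r} must touch exactly one species"
                    )
        if self.objective_id not in self._reactions_by_id:
            raise ModelConstructionError(
                f"objective reaction {self.objective_id!r} not in model"
            )

    # -- lookups -----------------------------------------------------------
    def get_species(self, sid: str) -> Species:
        return self._species_by_id[sid]

    def get_reaction(self, rid: str) -> Reaction:
        try:
            return self._reactions_by_id[rid]
        except KeyError:
            raise KeyError(f"no reaction with id {rid!r}") from None

    def has_reaction(self, rid: str) -> bool:
        return rid in self._reactions_by_id

    @property
    def species_ids(self) -> List[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    # -- stoichiometric matrix --------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """S with one row per species, one column per reaction."""
        s_index = {sid: i for i, sid in enumerate(self.species_ids)}
        S = np.zeros((len(self.species), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for sid, coef in r.stoichiometry.items():
                S[s_index[sid], j] = coef
        return S

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            species=list(self.species),
            reactions=[r.copy() for r in self.reactions],
            objective_id=self.objective_id,
            name=self.name,
        )


@dataclass(frozen=True)
class BiomassComposition:
    """Measured biomass composition driving the biomass objective.

    ``macro_fractions``: percent dry weight per macromolecule class
    (protein, carbohydrate, lipid, RNA, DNA, inorganic).  ``amino_acids``:
    umol per mg dry weight (used as relative molar proportions, rescaled
    to the protein mass fraction).
    """

    macro_fractions: Mapping[str, float]
    amino_acids: Mapping[str, float]
    lipid_profile: Mapping[str, float] = field(
        default_factory=lambda: {"palmitoyl": 2.0, "glycerophosphate": 1.0}
    )
    soluble_pool_and_ions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.macro_fractions.items():
            if v < 0:
                raise ValueError(f"macro fraction {k!r} negative: {v}")
        for k, v in self.amino_acids.items():
            if v < 0:
                raise ValueError(f"amino acid {k!r} negative mass: {v}")
        if sum(self.macro_fractions.values()) <= 0:
            raise ValueError("all-zero biomass composition")

    def normalized_fractions(self) -> Dict[str, float]:
        """Macro fractions renormalized to sum to 100 % dry weight."""
        total = sum(self.macro_fractions.values())
        return {k: 100.0 * v / total for k, v in self.macro_fractions.items()}


@dataclass(frozen=True)
class ETCStoichiometry:
    """Charge-equivalents translocated per 2 electrons for each
    respiratory complex, plus protons per ATP at the ATP synthase.

    Positive values mean charges moved out of the cytoplasm (building
    proton motive force) when the complex runs in its exergonic
    direction; reverse operation consumes the same number.
    """

    nxr_periplasmic_h: float = 2.0
    complex_iii: float = 4.0          # Q-cycle, both directions
    complex_i: float = 4.0            # NADH dehydrogenase
    complex_i_2m: float = 8.0         # ferredoxin-reducing 2M-type
    terminal_oxidase: float = 2.0     # bd-type, charge separation only
    h_per_atp: float = 4.0

    def __post_init__(self) -> None:
        for name in (
            "nxr_periplasmic_h",
            "complex_iii",
            "complex_i",
            "complex_i_2m",
            "terminal_oxidase",
            "h_per_atp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def calibrated_h_per_atp(self) -> float:
        """H+/ATP that makes the net nitrite ATP yield exactly 1.0.

        Per nitrite oxidized: the NXR releases ``nxr_periplasmic_h``
        protons in the periplasm and the terminal oxidase separates
        ``terminal_oxidase`` charges; nitrite electrons enter at
        cytochrome c so complex III is not in the span.
        """
        return self.nxr_periplasmic_h + self.terminal_oxidase


@dataclass(frozen=True)
class MaintenanceParams:
    """Growth-associated (mmol ATP gDW-1) and non-growth-associated
    (mmol ATP gDW-1 h-1) maintenance energy."""

    gam: float
    ngam: float

    def __post_init__(self) -> None:
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("maintenance parameters must be non-negative")


# ---------------------------------------------------------------------------
# balance checking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BalanceViolation:
    reaction_id: str
    element: str  # element symbol or "charge"
    residual: float


BalanceReport = List[BalanceViolation]

#: subsystems excluded from conservation checks (boundary or lumped-drain)
_UNCHECKED_SUBSYSTEMS = {"exchange", "biomass"}


def reaction_imbalance(
    reaction: Reaction, species_by_id: Mapping[str, Species], tol: float = 1e-6
) -> List[BalanceViolation]:
    """Element and charge residuals of one reaction (empty if balanced)."""
    residuals: Dict[str, float] = {el: 0.0 for el in ELEMENTS}
    charge = 0.0
    for sid, coef in reaction.stoichiometry.items():
        sp = species_by_id[sid]
        for el, n in (sp.formula or {}).items():
            residuals[el] = residuals.get(el, 0.0) + coef * n
        charge += coef * sp.charge
    out = [
        BalanceViolation(reaction.id, el, res)
        for el, res in residuals.items()
        if abs(res) > tol
    ]
    if abs(charge) > tol:
        out.append(BalanceViolation(reaction.id, "charge", charge))
    return out


def check_balance(model: MetabolicModel, tol: float = 1e-6) -> BalanceReport:
    """Mass/charge conservation report over all internal reactions.

    Exchange and biomass reactions are excluded by definition (they are
    boundary or lumped-mass drains).  A species with an *unknown* formula
    (``formula is None``) referenced by a checked reaction is flagged
    rather than silently skipped.
    """
    report: BalanceReport = []
    for r in model.reactions:
        if r.subsystem in _UNCHECKED_SUBSYSTEMS:
            continue
        for sid in r.stoichiometry:
            sp = model.get_species(sid)
            if sp.formula is None:
                report.append(BalanceViolation(r.id, f"unknown-formula:{sid}", np.nan))
        report.extend(reaction_imbalance(r, model._species_by_id, tol=tol))
    return report
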