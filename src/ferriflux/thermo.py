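"""Reaction free-energy ("thermodynamic ladder") engine.

Standard and in-situ Gibbs free energies for acetate-consuming iron-oxide
reduction and acetoclastic methanogenesis, normalized per mole of acetate.
In-situ energies follow

    dG = dG0 + R*T*ln(Q)

with Q the reaction quotient over aqueous, dissolved-gas and proton species;
solids and water contribute unit activity.  Concentrations are treated as
activities throughout (dilute freshwater convention); no activity-coefficient
model is applied.

The built-in :data:`REGISTRY` carries five reactions (magnetite,
ferrihydrite, goethite and hematite reduction, plus acetoclastic
methanogenesis) with their standard reaction energies in kJ per mole of
acetate, and every entry is element- and charge-balanced.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import bisect

__all__ = [
    "Phase",
    "SpeciesRef",
    "FormationEnergyTable",
    "ReactionSpec",
    "ChemicalConditions",
    "EnergyLandscape",
    "LadderRung",
    "MissingFormationEnergyError",
    "MissingActivityError",
    "ActivityDomainError",
    "REGISTRY",
    "SPECIES",
    "standard_reaction_energy",
    "log10_reaction_quotient",
    "delta_g",
    "sensitivity",
    "ladder",
    "crossover_activity",
    "landscape",
    "rt_ln10",
    "check_balance",
]

#: Default absolute temperature (K).
DEFAULT_T_K = 298.0
#: Gas constant in kJ mol^-1 K^-1.
DEFAULT_R_KJ = 8.314e-3

#: ties in the ladder closer than this (kJ/mol) keep registry order
LADDER_TIE_TOL = 1e-9


class MissingFormationEnergyError(KeyError):
    """A reaction species has no formation-energy entry."""


class MissingActivityError(KeyError):
    """A non-solid, non-water reaction species has no activity supplied."""


class ActivityDomainError(ValueError):
    """An activity is zero or negative."""


class Phase(str, enum.Enum):
    AQUEOUS = "aqueous"
    DISSOLVED_GAS = "dissolved-gas"
    WATER = "water"
    PROTON = "proton"
    SOLID = "solid"

    @property
    def unit_activity(self) -> bool:
        """Solids and water are excluded from reaction quotients."""
        return self in (Phase.SOLID, Phase.WATER)


@dataclass(frozen=True)
class SpeciesRef:
    """A chemical species participating in a reaction."""

    identifier: str
    phase: Phase

    def __post_init__(self) -> None:
        if not isinstance(self.phase, Phase):
            object.__setattr__(self, "phase", Phase(self.phase))


# element composition and charge used by the balance assertion
_COMPOSITION: dict[str, tuple[dict[str, int], int]] = {
    "Fe(OH)3": ({"Fe": 1, "O": 3, "H": 3}, 0),
    "FeOOH": ({"Fe": 1, "O": 2, "H": 1}, 0),
    "Fe2O3": ({"Fe": 2, "O": 3}, 0),
    "Fe3O4": ({"Fe": 3, "O": 4}, 0),
    "Fe2+": ({"Fe": 1}, 2),
    "acetate": ({"C": 2, "H": 3, "O": 2}, -1),
    "HCO3-": ({"C": 1, "H": 1, "O": 3}, -1),
    "CH4(aq)": ({"C": 1, "H": 4}, 0),
    "H+": ({"H": 1}, 1),
    "H2O": ({"H": 2, "O": 1}, 0),
}

#: Canonical species used by the built-in registry.
SPECIES: dict[str, SpeciesRef] = {
    "Fe(OH)3": SpeciesRef("Fe(OH)3", Phase.SOLID),
    "FeOOH": SpeciesRef("FeOOH", Phase.SOLID),
    "Fe2O3": SpeciesRef("Fe2O3", Phase.SOLID),
    "Fe3O4": SpeciesRef("Fe3O4", Phase.SOLID),
    "Fe2+": SpeciesRef("Fe2+", Phase.AQUEOUS),
    "acetate": SpeciesRef("acetate", Phase.AQUEOUS),
    "HCO3-": SpeciesRef("HCO3-", Phase.AQUEOUS),
    "CH4(aq)": SpeciesRef("CH4(aq)", Phase.DISSOLVED_GAS),
    "H+": SpeciesRef("H+", Phase.PROTON),
    "H2O": SpeciesRef("H2O", Phase.WATER),
}


@dataclass(frozen=True)
class ReactionSpec:
    """A stoichiometry map plus standard reaction energy.

    Products carry positive coefficients, reactants negative.
    ``delta_g_standard`` is in kJ per mole of reaction as written; registry
    entries are written per mole of acetate (acetate coefficient exactly -1).
    """

    name: str
    stoichiometry: Mapping[SpeciesRef, float]
    delta_g_standard: float

    def coefficient(self, identifier: str) -> float:
        for sp, coeff in self.stoichiometry.items():
            if sp.identifier == identifier:
                return coeff
        return 0.0

    def species(self) -> tuple[SpeciesRef, ...]:
        return tuple(self.stoichiometry)


def check_balance(
    rxn: ReactionSpec,
    composition: Mapping[str, tuple[Mapping[str, int], int]] | None = None,
    tol: float = 1e-9,
) -> None:
    """Assert element and charge balance of *rxn*.

    Raises ``ValueError`` naming the first unbalanced quantity.  Species
    without a composition entry raise ``KeyError``.
    """
    comp = _COMPOSITION if composition is None else composition
    totals: dict[str, float] = {}
    charge = 0.0
    for sp, coeff in rxn.stoichiometry.items():
        try:
            elements, z = comp[sp.identifier]
        except KeyError:
            raise KeyError(
                f"no composition known for species {sp.identifier!r}"
            ) from None
        charge += coeff * z
        for el, n in elements.items():
            totals[el] = totals.get(el, 0.0) + coeff * n
    for el, total in totals.items():
        if abs(total) > tol:
            raise ValueError(f"{rxn.name}: element {el} unbalanced by {total}")
    if abs(charge) > tol:
        raise ValueError(f"{rxn.name}: charge unbalanced by {charge}")


def _registry_reaction(name: str, stoich: dict[str, float], dg0: float) -> ReactionSpec:
    rxn = ReactionSpec(
        name=name,
        stoichiometry={SPECIES[k]: v for k, v in stoich.items()},
        delta_g_standard=dg0,
    )
    if rxn.coefficient("acetate") != -1:
        raise ValueError(f"{name}: registry entries are per mole acetate")
    check_balance(rxn)
    return rxn


#: Built-in acetate-consuming reactions, ordered from most to least
#: favorable at standard state.  Energies in kJ per mole acetate.
REGISTRY: tuple[ReactionSpec, ...] = (
    _registry_reaction(
        "magnetite reduction",
        {"Fe3O4": -4, "acetate": -1, "H+": -23, "Fe2+": 12, "HCO3-": 2, "H2O": 12},
        -546.47,
    ),
    _registry_reaction(
        "ferrihydrite reduction",
        {"Fe(OH)3": -8, "acetate": -1, "H+": -15, "Fe2+": 8, "HCO3-": 2, "H2O": 20},
        -510.83,
    ),
    _registry_reaction(
        "goethite reduction",
        {"FeOOH": -8, "acetate": -1, "H+": -15, "Fe2+": 8, "HCO3-": 2, "H2O": 12},
        -370.99,
    ),
    _registry_reaction(
        "hematite reduction",
        {"Fe2O3": -4, "acetate": -1, "H+": -15, "Fe2+": 8, "HCO3-": 2, "H2O": 8},
        -347.87,
    ),
    _registry_reaction(
        "methanogenesis",
        {"acetate": -1, "H2O": -1, "CH4(aq)": 1, "HCO3-": 1},
        -14.68,
    ),
)


def registry_by_name(name: str) -> ReactionSpec:
    for rxn in REGISTRY:
        if rxn.name == name:
            return rxn
    raise KeyError(name)


@dataclass(frozen=True)
class FormationEnergyTable:
    """Map species identifier -> standard formation energy (kJ/mol)."""

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        for key, val in self.values.items():
            if not math.isfinite(val):
                raise ValueError(f"non-finite formation energy for {key!r}")

    def __getitem__(self, identifier: str) -> float:
        try:
            return self.values[identifier]
        except KeyError:
            raise MissingFormationEnergyError(
                f"no formation energy for species {identifier!r}"
            ) from None

    def __contains__(self, identifier: str) -> bool:
        return identifier in self.values


@dataclass(frozen=True)
class ChemicalConditions:
    """Environmental conditions entering the reaction quotient.

    Proton activity is derived from ``pH`` as 10**(-pH); supplying ``H+`` in
    the activity map is rejected to prevent double specification.  Activities
    are dimensionless (concentration-as-activity convention) and must be
    strictly positive.
    """

    pH: float
    activities: Mapping[str, float] = field(default_factory=dict)
    temperature_K: float = DEFAULT_T_K
    gas_constant_R: float = DEFAULT_R_KJ

    def __post_init__(self) -> None:
        if "H+" in self.activities:
            raise ValueError("H+ is set through pH, not the activity map")
        for key, val in self.activities.items():
            if not (val > 0):
                raise ActivityDomainError(f"activity of {key!r} must be > 0, got {val}")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")

    @property
    def proton_activity(self) -> float:
        return 10.0 ** (-self.pH)

    def log10_activity(self, species: SpeciesRef) -> float:
        if species.phase is Phase.PROTON:
            return -self.pH
        try:
            a = self.activities[species.identifier]
        except KeyError:
            raise MissingActivityError(
                f"no activity supplied for species {species.identifier!r}"
            ) from None
        if not (a > 0):
            raise ActivityDomainError(
                f"activity of {species.identifier!r} must be > 0, got {a}"
            )
        return math.log10(a)

    def with_activity(self, identifier: str, activity: float) -> "ChemicalConditions":
        new = dict(self.activities)
        new[identifier] = activity
        return replace(self, activities=new)


def rt_ln10(cond: ChemicalConditions | None = None) -> float:
    """R*T*ln(10) in kJ/mol: the energy change per decade of activity."""
    if cond is None:
        return DEFAULT_R_KJ * DEFAULT_T_K * math.log(10.0)
    return cond.gas_constant_R * cond.temperature_K * math.log(10.0)


def standard_reaction_energy(table: FormationEnergyTable, rxn: ReactionSpec) -> float:
    """Standard reaction energy from formation energies: products minus
    reactants as a signed-coefficient dot product (kJ/mol as written)."""
    return sum(coeff * table[sp.identifier] for sp, coeff in rxn.stoichiometry.items())


def log10_reaction_quotient(rxn: ReactionSpec, cond: ChemicalConditions) -> float:
    """log10 of the reaction quotient Q.

    Sums coeff*log10(activity) over aqueous, dissolved-gas and proton
    species; solids and water are excluded (unit activity).
    """
    total = 0.0
    for sp, coeff in rxn.stoichiometry.items():
        if sp.phase.unit_activity:
            continue
        total += coeff * cond.log10_activity(sp)
    return total


def delta_g(rxn: ReactionSpec, cond: ChemicalConditions) -> float:
    """In-situ reaction energy dG0 + R*T*ln(10)*log10(Q), kJ per mole of
    reaction as written (per mole acetate for registry entries).  Negative
    values are exergonic."""
    return rxn.delta_g_standard + rt_ln10(cond) * log10_reaction_quotient(rxn, cond)


def sensitivity(
    rxn: ReactionSpec,
    species: SpeciesRef | str,
    cond: ChemicalConditions | None = None,
) -> float:
    """Slope of dG with respect to log10 activity of *species*
    (kJ/mol per decade *increase*).

    Equals coeff(species) * R*T*ln(10); exactly the finite difference of
    :func:`delta_g` across one decade.  For a product the slope is positive
    (dG rises with each decade increase); for a reactant it is negative, so
    the magnitude is the rise per decade *decrease*.  Species absent from
    the reaction give 0.
    """
    identifier = species.identifier if isinstance(species, SpeciesRef) else species
    coeff = rxn.coefficient(identifier)
    return coeff * rt_ln10(cond)


@dataclass(frozen=True)
class LadderRung:
    reaction: ReactionSpec
    delta_g: float


def ladder(
    rxns: Sequence[ReactionSpec], cond: ChemicalConditions
) -> list[LadderRung]:
    """Rank reactions from most to least favorable (ascending dG).

    The sort is stable; dG values closer than ``LADDER_TIE_TOL`` are treated
    as tied and keep input (registry) order.
    """
    if not rxns:
        raise ValueError("ladder requires at least one reaction")
    rungs = [LadderRung(rxn, delta_g(rxn, cond)) for rxn in rxns]
    order = sorted(range(len(rungs)), key=lambda i: rungs[i].delta_g)
    # restore input order inside near-tied runs
    for k in range(1, len(order)):
        j = k
        while (
            j > 0
            and abs(rungs[order[j]].delta_g - rungs[order[j - 1]].delta_g)
            <= LADDER_TIE_TOL
            and order[j] < order[j - 1]
        ):
            order[j], order[j - 1] = order[j - 1], order[j]
            j -= 1
    return [rungs[i] for i in order]


def crossover_activity(
    rxn_a: ReactionSpec,
    rxn_b: ReactionSpec,
    variable: SpeciesRef | str,
    cond: ChemicalConditions,
    bracket: tuple[float, float],
    xtol: float = 1e-6,
) -> float | None:
    """log10 activity of *variable* at which dG of the two reactions cross.

    All other activities are fixed at *cond*.  The root of
    ``delta_g(rxn_a) - delta_g(rxn_b)`` is located by bisection within the
    log10 *bracket* to *xtol* log units.  Returns ``None`` when the bracket
    shows no sign change, or when the difference is degenerate (identically
    zero across the bracket, e.g. comparing a reaction with itself).
    """
    identifier = variable.identifier if isinstance(variable, SpeciesRef) else variable
    lo, hi = bracket
    if not (math.isfinite(lo) and math.isfinite(hi)) or lo >= hi:
        raise ValueError(f"invalid log10 bracket {bracket}")
    ca, cb = rxn_a.coefficient(identifier), rxn_b.coefficient(identifier)
    if ca == 0 and cb == 0:
        raise ValueError(
            f"species {identifier!r} appears in neither reaction"
        )

    def diff(x: float) -> float:
        c = cond.with_activity(identifier, 10.0**x)
        return delta_g(rxn_a, c) - delta_g(rxn_b, c)

    f_lo, f_hi = diff(lo), diff(hi)
    if abs(f_lo) < 1e-12 and abs(f_hi) < 1e-12:
        return None  # degenerate: identically equal
    if f_lo == 0:
        return lo
    if f_hi == 0:
        return hi
    if f_lo * f_hi > 0:
        return None
    return float(bisect(diff, lo, hi, xtol=xtol))


@dataclass(frozen=True)
class LandscapeAxis:
    """One swept species with its ordered log10-activity grid."""

    species: str
    log10_activities: tuple[float, ...]

    def __post_init__(self) -> None:
        grid = tuple(float(x) for x in self.log10_activities)
        if len(grid) == 0:
            raise ValueError("empty landscape axis")
        object.__setattr__(self, "log10_activities", grid)


@dataclass(frozen=True)
class EnergyLandscape:
    """dG evaluated on a 1- or 2-axis log10-activity grid.

    ``values`` has shape ``(n_reactions, *grid shape)`` in kJ/mol acetate.
    Along any axis dG is monotone with the sign of that species'
    stoichiometric coefficient.
    """

    reactions: tuple[str, ...]
    axes: tuple[LandscapeAxis, ...]
    values: np.ndarray

    def to_frame(self):
        """Long-format table: reaction, one column per axis, delta_g."""
        import pandas as pd

        rows = []
        grids = [ax.log10_activities for ax in self.axes]
        for i, name in enumerate(self.reactions):
            for idx in np.ndindex(*(len(g) for g in grids)):
                row = {"reaction": name}
                for ax, g, j in zip(self.axes, grids, idx):
                    row[f"log10_{ax.species}"] = g[j]
                row["delta_g_kj_per_mol"] = float(self.values[(i, *idx)])
                rows.append(row)
        return pd.DataFrame(rows)


def landscape(
    rxns: Sequence[ReactionSpec],
    axes: Sequence[LandscapeAxis],
    cond: ChemicalConditions,
) -> EnergyLandscape:
    """Evaluate dG for each reaction over a 1- or 2-axis activity grid.

    Axis species must not also appear in the fixed activity map of *cond*.
    Off-axis activities come from *cond*; the grid contribution is added
    analytically via the per-decade slope.
    """
    if not 1 <= len(axes) <= 2:
        raise ValueError("landscape supports 1 or 2 axes")
    names = [ax.species for ax in axes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate landscape axis species")
    for name in names:
        if name in cond.activities:
            raise ValueError(
                f"axis species {name!r} also has a fixed activity in conditions"
            )

    # base: every axis species at unit activity (log10 = 0)
    base = cond
    for name in names:
        base = base.with_activity(name, 1.0)
    slope = rt_ln10(cond)
    grids = [np.asarray(ax.log10_activities, dtype=float) for ax in axes]
    mesh = np.meshgrid(*grids, indexing="ij")
    values = np.empty((len(rxns), *mesh[0].shape), dtype=float)
    for i, rxn in enumerate(rxns):
        dg0 = delta_g(rxn, base)
        surface = np.full(mesh[0].shape, dg0)
        for name, m in zip(names, mesh):
            surface = surface + rxn.coefficient(name) * slope * m
        values[i] = surface
    return EnergyLandscape(
        reactions=tuple(r.name for r in rxns),
        axes=tuple(axes),
        values=values,
    )


#: Footnote conditions used for the in-situ columns of the built-in table:
#: pH 7, (HCO3-) = 0.01, (Fe2+) = 0.001, [CH4(aq)] = 1e-5.
def table_conditions(acetate_activity: float) -> ChemicalConditions:
    return ChemicalConditions(
        pH=7.0,
        activities={
            "HCO3-": 0.01,
            "Fe2+": 0.001,
            "CH4(aq)": 1e-5,
            "acetate": acetate_activity,
        },
    )
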