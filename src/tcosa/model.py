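"""Core data structures for cofactor-swap thermodynamic analysis.

The central objects are a plain stoichiometric :class:`MetabolicModel`, a
:class:`ThermoAnnotation` carrying standard reaction Gibbs energies and
metabolite concentration bounds, a :class:`CofactorSpec` naming the redox
cofactor pools, and the reconfigured :class:`TcosaModel` in which every
reversible reaction has been split into irreversible forward/backward copies
and every redox reaction duplicated (or triplicated) with the alternative
cofactor pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ThermoAnnotation",
    "CofactorSpec",
    "ReactionProvenance",
    "TcosaModel",
    "Tag",
    "ModelError",
    "ConfigurationError",
    "GAS_CONSTANT_KJ",
    "DEFAULT_TEMPERATURE_K",
    "FARADAY_KJ_PER_V",
]

#: Gas constant in kJ mol^-1 K^-1.
GAS_CONSTANT_KJ = 8.314e-3
#: Reference temperature in K.
DEFAULT_TEMPERATURE_K = 298.15
#: Faraday constant in kJ V^-1 mol^-1.
FARADAY_KJ_PER_V = 96.485


class ModelError(ValueError):
    """A model violates a structural invariant (e.g. lb > ub)."""


class ConfigurationError(ValueError):
    """Inconsistent user configuration (missing objective, unknown ids ...)."""


class Tag:
    """Provenance tags for standard Gibbs energy values."""

    COMPUTED = "computed"
    DEFAULT_SENTINEL = "default_sentinel"
    MEDIAN_IMPUTED = "median_imputed"
    RELAXED = "relaxed"
    UNCONSTRAINED = "unconstrained"


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str = "c"
    external: bool = False


@dataclass
class Reaction:
    """A reaction with sparse stoichiometry (negative = substrate)."""

    id: str
    stoich: dict[str, float]
    lb: float = 0.0
    ub: float = 1000.0

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    def substrates(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoich.items() if c < 0}

    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoich.items() if c > 0}

    def reversed(self, new_id: str) -> "Reaction":
        return Reaction(
            id=new_id,
            stoich={m: -c for m, c in self.stoich.items()},
            lb=max(0.0, -self.ub),
            ub=-self.lb,
        )

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoich), self.lb, self.ub)


@dataclass
class MetabolicModel:
    """A constraint-based metabolic network.

    Parameters
    ----------
    metabolites:
        Mapping id -> :class:`Metabolite`. Metabolites flagged ``external``
        are not mass-balanced but still appear in driving-force terms.
    reactions:
        Mapping id -> :class:`Reaction` (insertion order is preserved and
        defines the column order of the stoichiometric matrix).
    objective_reaction_id:
        Growth/objective pseudo-reaction id.
    exchange_reaction_ids:
        Boundary pseudo-reactions. If empty, single-metabolite reactions
        are auto-detected as exchanges by :func:`detect_exchanges`.
    """

    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    objective_reaction_id: str
    exchange_reaction_ids: set[str] = field(default_factory=set)

    def validate(self) -> None:
        if self.objective_reaction_id not in self.reactions:
            raise ConfigurationError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )
        for rxn in self.reactions.values():
            if not rxn.lb <= rxn.ub:
                raise ModelError(f"reaction {rxn.id!r}: lb {rxn.lb} > ub {rxn.ub}")
            for met, coef in rxn.stoich.items():
                if met not in self.metabolites:
                    raise ModelError(f"reaction {rxn.id!r}: unknown metabolite {met!r}")
                if coef == 0 or not math.isfinite(coef):
                    raise ModelError(
                        f"reaction {rxn.id!r}: invalid coefficient {coef} for {met!r}"
                    )

    def detect_exchanges(self) -> set[str]:
        """Single-metabolite boundary reactions (plus declared ones)."""
        auto = {r.id for r in self.reactions.values() if len(r.stoich) == 1}
        return auto | set(self.exchange_reaction_ids)

    def internal_metabolites(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if not m.external]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=dict(self.metabolites),
            reactions={rid: r.copy() for rid, r in self.reactions.items()},
            objective_reaction_id=self.objective_reaction_id,
            exchange_reaction_ids=set(self.exchange_reaction_ids),
        )


@dataclass
class ThermoAnnotation:
    """Thermodynamic data attached to a model.

    ``dG0`` holds standard reaction Gibbs energies in kJ/mol; reactions
    without an entry are thermodynamically unconstrained (exchanges, growth)
    or will receive a sentinel/median value during reconfiguration, recorded
    in ``dG0_source_tag``. Concentration bounds are molar; metabolites
    absent from ``c_min``/``c_max`` use the default range (1e-6 M, 0.02 M).
    Species in ``fixed_unit_species`` (protons, water) are pinned to 1 M
    because their contribution is already folded into the dG0 values.
    """

    dG0: dict[str, float] = field(default_factory=dict)
    dG0_source_tag: dict[str, str] = field(default_factory=dict)
    c_min: dict[str, float] = field(default_factory=dict)
    c_max: dict[str, float] = field(default_factory=dict)
    temperature: float = DEFAULT_TEMPERATURE_K
    gas_constant: float = GAS_CONSTANT_KJ
    fixed_unit_species: set[str] = field(default_factory=set)
    default_c_min: float = 1e-6
    default_c_max: float = 0.02

    @property
    def RT(self) -> float:
        return self.gas_constant * self.temperature

    def conc_bounds(self, met_id: str) -> tuple[float, float]:
        if met_id in self.fixed_unit_species:
            return (1.0, 1.0)
        return (
            self.c_min.get(met_id, self.default_c_min),
            self.c_max.get(met_id, self.default_c_max),
        )

    def validate(self, model: MetabolicModel | None = None) -> None:
        if self.temperature <= 0:
            raise ModelError("temperature must be positive")
        mets = self.metabolites_with_bounds(model)
        for m in mets:
            lo, hi = self.conc_bounds(m)
            if not (0 < lo <= hi):
                raise ModelError(f"metabolite {m!r}: invalid concentration bounds ({lo}, {hi})")

    def metabolites_with_bounds(self, model: MetabolicModel | None) -> list[str]:
        if model is not None:
            return list(model.metabolites)
        return sorted(set(self.c_min) | set(self.c_max) | self.fixed_unit_species)

    def copy(self) -> "ThermoAnnotation":
        return replace(
            self,
            dG0=dict(self.dG0),
            dG0_source_tag=dict(self.dG0_source_tag),
            c_min=dict(self.c_min),
            c_max=dict(self.c_max),
            fixed_unit_species=set(self.fixed_unit_species),
        )


@dataclass
class CofactorSpec:
    """Named redox cofactor pools as (oxidized, reduced) metabolite pairs.

    Defaults follow BiGG ids for the cytosolic NAD(H)/NADP(H) couples.
    """

    pools: dict[str, tuple[str, str]] = field(
        default_factory=lambda: {
            "NAD": ("nad_c", "nadh_c"),
            "NADP": ("nadp_c", "nadph_c"),
        }
    )

    def validate(self) -> None:
        if not self.pools:
            raise ConfigurationError("at least one cofactor pool must be defined")
        seen: set[str] = set()
        for name, (ox, red) in self.pools.items():
            for met in (ox, red):
                if met in seen:
                    raise ConfigurationError(f"cofactor metabolite {met!r} used twice")
                seen.add(met)

    def species(self) -> set[str]:
        out: set[str] = set()
        for ox, red in self.pools.values():
            out |= {ox, red}
        return out

    def pools_used(self, rxn: Reaction) -> set[str]:
        """Names of pools whose members occur in the reaction."""
        return {
            name
            for name, (ox, red) in self.pools.items()
            if ox in rxn.stoich or red in rxn.stoich
        }


@dataclass(frozen=True)
class ReactionProvenance:
    original_id: str
    direction: str = "FWD"  # FWD or REV
    pool: str | None = None  # cofactor pool tag, None for non-redox reactions
    is_variant: bool = False  # True for the introduced swapped-cofactor copy


@dataclass
class TcosaModel:
    """An irreversible, cofactor-expanded network ready for the MDF MILPs.

    ``variant_groups`` maps each original (pre-split) reaction id to the
    derived reaction ids (forward/backward splits x cofactor variants); at
    most one member of each group with >= 2 members may carry flux in any
    solution. ``thermo_active`` is False for exchange/growth pseudo-reactions
    and for reactions whose driving-force constraint was relaxed.
    """

    network: MetabolicModel
    thermo: ThermoAnnotation
    cofactors: CofactorSpec
    variant_groups: dict[str, list[str]] = field(default_factory=dict)
    provenance: dict[str, ReactionProvenance] = field(default_factory=dict)
    thermo_active: dict[str, bool] = field(default_factory=dict)
    dual_cofactor_reaction_ids: set[str] = field(default_factory=set)

    def validate(self) -> None:
        self.network.validate()
        self.thermo.validate(self.network)
        for rxn in self.network.reactions.values():
            if rxn.lb < 0:
                raise ModelError(f"reaction {rxn.id!r} not irreversible (lb={rxn.lb})")
            if self.thermo_active.get(rxn.id, False) and rxn.id not in self.thermo.dG0:
                raise ModelError(f"thermo-active reaction {rxn.id!r} lacks a dG0")
        for orig, members in self.variant_groups.items():
            for rid in members:
                if rid not in self.network.reactions:
                    raise ModelError(f"variant group {orig!r}: unknown member {rid!r}")

    def duplicated_originals(self) -> list[str]:
        """Original reaction ids that possess swapped-cofactor variants."""
        out = []
        for orig, members in self.variant_groups.items():
            if any(self.provenance[m].is_variant for m in members):
                out.append(orig)
        return out

    def variants_by_pool(self, original_id: str) -> dict[str, list[str]]:
        """Group a reaction's derived copies by cofactor pool tag."""
        by_pool: dict[str, list[str]] = {}
        for rid in self.variant_groups.get(original_id, []):
            pool = self.provenance[rid].pool
            if pool is not None:
                by_pool.setdefault(pool, []).append(rid)
        return by_pool

    def copy(self) -> "TcosaModel":
        return TcosaModel(
            network=self.network.copy(),
            thermo=self.thermo.copy(),
            cofactors=self.cofactors,
            variant_groups={k: list(v) for k, v in self.variant_groups.items()},
            provenance=dict(self.provenance),
            thermo_active=dict(self.thermo_active),
            dual_cofactor_reaction_ids=set(self.dual_cofactor_reaction_ids),
        )
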