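"""Model reconfiguration for cofactor-swap analysis.

The pipeline turns a plain stoichiometric model into a :class:`TcosaModel`:

1. :func:`assign_default_dG` — sentinel dG0 for reactions without a computed
   value and for pure transporters; exchanges and growth stay unconstrained.
2. :func:`impute_redox_dG_medians` — median dG0 per cofactor substrate
   species for redox reactions lacking a computed value.
3. :func:`split_reversible` — every reversible reaction becomes a forward
   and a backward irreversible copy.
4. :func:`duplicate_redox_reactions` / :func:`triplicate_redox_reactions` —
   every redox reaction gains copies with the alternative cofactor pool(s).
5. :func:`relax_to_feasibility` — minimal set of driving-force constraints
   to drop so a demanded growth rate becomes thermodynamically feasible.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from .model import (
    FARADAY_KJ_PER_V,
    CofactorSpec,
    ConfigurationError,
    MetabolicModel,
    ModelError,
    Reaction,
    ReactionProvenance,
    Tag,
    TcosaModel,
    ThermoAnnotation,
)

__all__ = [
    "DEFAULT_SENTINEL_DG0",
    "split_reversible",
    "assign_default_dG",
    "impute_redox_dG_medians",
    "duplicate_redox_reactions",
    "triplicate_redox_reactions",
    "redox_potential_to_dG_shift",
    "relax_to_feasibility",
    "prepare_tcosa_model",
    "ImputationError",
]

#: Default sentinel standard Gibbs energy (kJ/mol) for reactions without a
#: computed value; low enough to impose only weak concentration constraints.
DEFAULT_SENTINEL_DG0 = -100.0


class ImputationError(ValueError):
    """No computed dG0 available for a cofactor species needing a median."""


def redox_potential_to_dG_shift(dE_mV: float, n_electrons: int) -> float:
    """Gibbs energy change (kJ/mol) equivalent to a redox potential ``dE``.

    Returns ``-n * F * dE`` with the Faraday constant in kJ V^-1 mol^-1;
    e.g. the NAD(P)H/NAD(P)+ couple at -320 mV with n = 2 corresponds to a
    formation-energy difference of 61.75 kJ/mol between reduced and
    oxidized form.
    """
    if n_electrons < 1:
        raise ConfigurationError("n_electrons must be >= 1")
    return -n_electrons * FARADAY_KJ_PER_V * dE_mV / 1000.0


def _is_pure_transporter(rxn: Reaction, model: MetabolicModel) -> bool:
    """True when reactants equal products up to the compartment suffix."""

    def stripped(met_id: str) -> str:
        met = model.metabolites.get(met_id)
        if met is not None and met_id.endswith(f"_{met.compartment}"):
            return met_id[: -(len(met.compartment) + 1)]
        return met_id

    subs = sorted((stripped(m), abs(c)) for m, c in rxn.stoich.items() if c < 0)
    prods = sorted((stripped(m), abs(c)) for m, c in rxn.stoich.items() if c > 0)
    return bool(subs) and subs == prods


def assign_default_dG(
    model: MetabolicModel,
    thermo: ThermoAnnotation,
    sentinel: float = DEFAULT_SENTINEL_DG0,
) -> ThermoAnnotation:
    """Fill in dG0 tags: computed values keep theirs, transporters and
    unannotated reactions get the sentinel, exchanges/growth stay free."""
    out = thermo.copy()
    exchanges = model.detect_exchanges()
    for rxn in model.reactions.values():
        rid = rxn.id
        if rid == model.objective_reaction_id or rid in exchanges:
            out.dG0.pop(rid, None)
            out.dG0_source_tag[rid] = Tag.UNCONSTRAINED
        elif _is_pure_transporter(rxn, model) or rid not in out.dG0:
            out.dG0[rid] = sentinel
            out.dG0_source_tag[rid] = Tag.DEFAULT_SENTINEL
        elif out.dG0_source_tag.get(rid, Tag.COMPUTED) == Tag.COMPUTED:
            out.dG0_source_tag[rid] = Tag.COMPUTED
    return out


def impute_redox_dG_medians(
    model: MetabolicModel,
    thermo: ThermoAnnotation,
    cofactors: CofactorSpec,
) -> ThermoAnnotation:
    """Median-impute dG0 for redox reactions lacking a computed value.

    For every cofactor species (oxidized and reduced member of each pool),
    the median dG0 over all computed-dG0 reactions consuming that species
    is determined; a redox reaction without a computed dG0 then receives
    the median of the cofactor species it consumes. Must be applied to the
    pre-split reaction set so forward/backward copies are not double
    counted.
    """
    cofactors.validate()
    out = thermo.copy()
    species = cofactors.species()

    medians: dict[str, float] = {}
    for sp in species:
        vals = [
            out.dG0[r.id]
            for r in model.reactions.values()
            if out.dG0_source_tag.get(r.id) == Tag.COMPUTED
            and r.stoich.get(sp, 0) < 0
        ]
        if vals:
            medians[sp] = statistics.median(vals)

    for rxn in model.reactions.values():
        tag = out.dG0_source_tag.get(rxn.id)
        if tag in (Tag.COMPUTED, Tag.UNCONSTRAINED):
            continue
        consumed = [sp for sp in species if rxn.stoich.get(sp, 0) < 0]
        if not consumed:
            continue
        needed = []
        for sp in consumed:
            if sp not in medians:
                raise ImputationError(
                    f"no computed dG0 for any reaction consuming {sp!r}"
                )
            needed.append(medians[sp])
        out.dG0[rxn.id] = statistics.fmean(needed)
        out.dG0_source_tag[rxn.id] = Tag.MEDIAN_IMPUTED
    return out


def split_reversible(
    model: MetabolicModel, thermo: ThermoAnnotation
) -> tuple[MetabolicModel, ThermoAnnotation]:
    """Split every reversible reaction into irreversible FWD/REV copies.

    The backward copy has negated stoichiometry and bounds [0, -lb]; its
    dG0 is negated, except for sentinel-tagged values, which keep the
    sentinel in both directions so neither direction is favored.
    """
    out_rxns: dict[str, Reaction] = {}
    out_thermo = thermo.copy()
    objective = model.objective_reaction_id
    exchanges = set(model.exchange_reaction_ids)

    for rxn in model.reactions.values():
        if not rxn.reversible:
            out_rxns[rxn.id] = rxn.copy()
            continue
        fwd = Reaction(f"{rxn.id}_FWD", dict(rxn.stoich), 0.0, max(0.0, rxn.ub))
        rev = Reaction(
            f"{rxn.id}_REV", {m: -c for m, c in rxn.stoich.items()}, 0.0, -rxn.lb
        )
        out_rxns[fwd.id] = fwd
        out_rxns[rev.id] = rev
        tag = out_thermo.dG0_source_tag.pop(rxn.id, None)
        dG0 = out_thermo.dG0.pop(rxn.id, None)
        if tag is not None:
            out_thermo.dG0_source_tag[fwd.id] = tag
            out_thermo.dG0_source_tag[rev.id] = tag
        if dG0 is not None:
            out_thermo.dG0[fwd.id] = dG0
            out_thermo.dG0[rev.id] = dG0 if tag == Tag.DEFAULT_SENTINEL else -dG0
        if rxn.id == objective:
            objective = fwd.id
        if rxn.id in exchanges:
            exchanges.discard(rxn.id)
            exchanges |= {fwd.id, rev.id}

    out_model = MetabolicModel(
        metabolites=dict(model.metabolites),
        reactions=out_rxns,
        objective_reaction_id=objective,
        exchange_reaction_ids=exchanges,
    )
    out_model.validate()
    return out_model, out_thermo


def _base_original(rid: str) -> tuple[str, str]:
    """Recover (original pre-split id, direction) from the naming scheme."""
    if rid.endswith("_FWD"):
        return rid[:-4], "FWD"
    if rid.endswith("_REV"):
        return rid[:-4], "REV"
    return rid, "FWD"


def _expand_cofactor_variants(
    model: MetabolicModel,
    thermo: ThermoAnnotation,
    cofactors: CofactorSpec,
    dG0_shift_per_pool: dict[str, float],
) -> TcosaModel:
    """Shared implementation of duplication/triplication.

    For each split, irreversible reaction using exactly one cofactor pool
    P, the reaction is renamed ``<orig>_ORIGINAL_<P>[_FWD|_REV]_TCOSA`` and,
    for every other pool Q, a copy ``<orig>_VARIANT_<Q>[_FWD|_REV]_TCOSA``
    is created with oxidized<->oxidized and reduced<->reduced substitution
    at identical coefficients and bounds. The variant inherits the dG0
    unchanged except for a per-pool shift (signed coefficient of the
    oxidized cofactor times the pool's formation-energy offset) used for
    hypothetical third cofactors with a different redox potential.
    Reactions touching two or more pools simultaneously are never
    duplicated.
    """
    cofactors.validate()
    for name, (ox, red) in cofactors.pools.items():
        for met in (ox, red):
            if met not in model.metabolites:
                raise ConfigurationError(
                    f"cofactor metabolite {met!r} (pool {name}) not in model"
                )

    out_rxns: dict[str, Reaction] = {}
    out_thermo = thermo.copy()
    provenance: dict[str, ReactionProvenance] = {}
    variant_groups: dict[str, list[str]] = {}
    dual: set[str] = set()
    exchanges = set(model.exchange_reaction_ids)
    objective = model.objective_reaction_id
    rename: dict[str, str] = {}
    all_exchanges = model.detect_exchanges()

    for rxn in model.reactions.values():
        orig, direction = _base_original(rxn.id)
        pools = cofactors.pools_used(rxn)
        dirsuffix = "" if rxn.id == orig else f"_{direction}"

        if len(pools) >= 2:
            dual.add(rxn.id)
        if len(pools) != 1 or rxn.id == objective or rxn.id in all_exchanges:
            out_rxns[rxn.id] = rxn.copy()
            provenance[rxn.id] = ReactionProvenance(orig, direction, None, False)
            variant_groups.setdefault(orig, []).append(rxn.id)
            continue

        (home_pool,) = pools
        new_id = f"{orig}_ORIGINAL_{home_pool}{dirsuffix}_TCOSA"
        renamed = rxn.copy()
        renamed.id = new_id
        out_rxns[new_id] = renamed
        rename[rxn.id] = new_id
        provenance[new_id] = ReactionProvenance(orig, direction, home_pool, False)
        variant_groups.setdefault(orig, []).append(new_id)
        if rxn.id in out_thermo.dG0:
            out_thermo.dG0[new_id] = out_thermo.dG0.pop(rxn.id)
            out_thermo.dG0_source_tag[new_id] = out_thermo.dG0_source_tag.pop(rxn.id)
        ox_home, red_home = cofactors.pools[home_pool]

        for other_pool, (ox_o, red_o) in cofactors.pools.items():
            if other_pool == home_pool:
                continue
            var_id = f"{orig}_VARIANT_{other_pool}{dirsuffix}_TCOSA"
            stoich = dict(renamed.stoich)
            for src, dst in ((ox_home, ox_o), (red_home, red_o)):
                if src in stoich:
                    stoich[dst] = stoich.pop(src)
            out_rxns[var_id] = Reaction(var_id, stoich, renamed.lb, renamed.ub)
            provenance[var_id] = ReactionProvenance(orig, direction, other_pool, True)
            variant_groups.setdefault(orig, []).append(var_id)
            if new_id in out_thermo.dG0:
                shift = dG0_shift_per_pool.get(other_pool, 0.0) - dG0_shift_per_pool.get(
                    home_pool, 0.0
                )
                nu_ox = renamed.stoich.get(ox_home, 0.0)
                out_thermo.dG0[var_id] = out_thermo.dG0[new_id] - shift * nu_ox
                out_thermo.dG0_source_tag[var_id] = out_thermo.dG0_source_tag[new_id]

    if objective in rename:
        objective = rename[objective]

    out_model = MetabolicModel(
        metabolites=dict(model.metabolites),
        reactions=out_rxns,
        objective_reaction_id=objective,
        exchange_reaction_ids={rename.get(e, e) for e in exchanges},
    )
    out_model.validate()

    exchange_like = out_model.detect_exchanges() | {objective}
    thermo_active = {
        rid: (
            rid not in exchange_like
            and out_thermo.dG0_source_tag.get(rid) not in (Tag.UNCONSTRAINED, Tag.RELAXED)
            and rid in out_thermo.dG0
        )
        for rid in out_rxns
    }

    tcosa = TcosaModel(
        network=out_model,
        thermo=out_thermo,
        cofactors=cofactors,
        variant_groups=variant_groups,
        provenance=provenance,
        thermo_active=thermo_active,
        dual_cofactor_reaction_ids=dual,
    )
    tcosa.validate()
    return tcosa


def duplicate_redox_reactions(
    model: MetabolicModel,
    thermo: ThermoAnnotation,
    cofactors: CofactorSpec,
) -> TcosaModel:
    """Duplicate every single-pool redox reaction with the alternative pool.

    Requires an already-split (irreversible) model and exactly two pools.
    The two pools are assumed to have identical standard redox potential,
    so the swapped copy inherits the dG0 unchanged.
    """
    if len(cofactors.pools) != 2:
        raise ConfigurationError("duplication requires exactly two cofactor pools")
    return _expand_cofactor_variants(model, thermo, cofactors, {})


def triplicate_redox_reactions(
    model: MetabolicModel,
    thermo: ThermoAnnotation,
    cofactors: CofactorSpec,
    dE_shift_mV: float = 0.0,
    n_electrons: int = 2,
    third_pool: str = "NADZ",
) -> TcosaModel:
    """Add a hypothetical third cofactor pool with a shifted redox potential.

    ``dE_shift_mV`` is the shift of the third couple's standard redox
    potential relative to NAD(P)H/NAD(P)+ (negative = lower potential, i.e.
    a stronger electron donor). Reducing the third couple then costs more
    energy: each third-pool variant's dG0 moves by ``-n F dE`` times the
    (signed, negated) stoichiometric coefficient of the oxidized cofactor.
    The third pool's metabolites are added to the model if absent.
    """
    if third_pool not in cofactors.pools:
        raise ConfigurationError(f"cofactor spec lacks the third pool {third_pool!r}")
    if len(cofactors.pools) != 3:
        raise ConfigurationError("triplication requires exactly three cofactor pools")
    model = model.copy()
    from .model import Metabolite

    for met in cofactors.pools[third_pool]:
        if met not in model.metabolites:
            model.metabolites[met] = Metabolite(met, compartment="c", external=False)
    shift = redox_potential_to_dG_shift(dE_shift_mV, n_electrons)
    return _expand_cofactor_variants(model, thermo, cofactors, {third_pool: shift})


def relax_to_feasibility(
    tcosa: TcosaModel,
    demanded_growth: float,
    B_min: float = 0.1,
    config=None,
):
    """Drop the fewest driving-force constraints to reach ``B >= B_min``.

    Solves a MILP minimizing the number of thermo-active reactions whose
    driving-force constraint is removed while the demanded growth rate is
    met. Returns ``(relaxed_ids, new_model)`` where the new model has the
    chosen reactions retagged as relaxed (thermodynamically unconstrained
    in all subsequent analyses). Raises on stoichiometric infeasibility.
    """
    from .milp import MilpConfig, solve_min_relaxation

    if config is None:
        config = MilpConfig()
    relaxed = solve_min_relaxation(tcosa, demanded_growth, B_min, config)
    out = tcosa.copy()
    for rid in relaxed:
        out.thermo_active[rid] = False
        out.thermo.dG0_source_tag[rid] = Tag.RELAXED
        out.thermo.dG0.pop(rid, None)
    return relaxed, out


@dataclass
class PrepareOptions:
    sentinel: float = DEFAULT_SENTINEL_DG0
    third_cofactor_dE_mV: float | None = None
    n_electrons: int = 2


def prepare_tcosa_model(
    model: MetabolicModel,
    thermo: ThermoAnnotation,
    cofactors: CofactorSpec,
    options: PrepareOptions | None = None,
) -> TcosaModel:
    """Full reconfiguration pipeline: defaults, medians, split, duplication
    (or triplication when a third-cofactor potential shift is given)."""
    options = options or PrepareOptions()
    model.validate()
    thermo = assign_default_dG(model, thermo, options.sentinel)
    thermo = impute_redox_dG_medians(model, thermo, _two_pool_view(cofactors))
    split_model, split_thermo = split_reversible(model, thermo)
    if options.third_cofactor_dE_mV is None:
        two_pool = _two_pool_view(cofactors)
        return duplicate_redox_reactions(split_model, split_thermo, two_pool)
    return triplicate_redox_reactions(
        split_model,
        split_thermo,
        cofactors,
        dE_shift_mV=options.third_cofactor_dE_mV,
        n_electrons=options.n_electrons,
    )


def _two_pool_view(cofactors: CofactorSpec) -> CofactorSpec:
    """The NAD/NADP pools of a spec that may also define a third pool."""
    if len(cofactors.pools) == 2:
        return cofactors
    kept = {k: v for k, v in cofactors.pools.items() if k != "NADZ"}
    if len(kept) != 2:
        raise ConfigurationError("cannot identify the two native pools")
    return CofactorSpec(pools=kept)
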