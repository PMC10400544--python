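"""Synthetic toy networks with known thermodynamics.

These generators produce small, fully specified metabolic models used
throughout the test-suite and the examples: linear pathways with
closed-form MDF values, a catabolic/anabolic redox fixture in which an
NAD+-reducing and an NADPH-consuming reaction must run simultaneously,
and seeded random networks small enough for the exhaustive enumeration
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    CofactorSpec,
    ConfigurationError,
    MetabolicModel,
    Metabolite,
    Reaction,
    ThermoAnnotation,
)

__all__ = [
    "StepSpec",
    "ToyNetworkSpec",
    "generate_toy",
    "linear_chain",
    "redox_fixture",
    "random_toy",
    "TOY_POOLS",
]

#: Cofactor ids used by all toy networks (no compartment suffix).
TOY_POOLS = {"NAD": ("nad", "nadh"), "NADP": ("nadp", "nadph")}


@dataclass
class StepSpec:
    """One enzymatic conversion ``substrate -> product``.

    When ``pool`` is set, the step is redox-coupled: mode ``"reduce"``
    additionally converts the pool's oxidized into its reduced form (the
    step oxidizes its substrate), mode ``"oxidize"`` the reverse, with
    ``cof_coef`` cofactor molecules per conversion.
    """

    id: str
    substrate: str
    product: str
    dG0: float = 0.0
    pool: str | None = None
    mode: str = "reduce"
    cof_coef: float = 1.0
    reversible: bool = False
    ub: float = 1000.0


@dataclass
class ToyNetworkSpec:
    """Declarative description of a toy network.

    ``biomass`` is the sink stoichiometry (negative = consumed); the sink
    is the objective reaction. ``recycle_dG0`` adds one regeneration
    reaction (reduced -> oxidized) per listed pool so redox-coupled steps
    can run at steady state.
    """

    steps: list[StepSpec] = field(default_factory=list)
    uptakes: dict[str, float] = field(default_factory=dict)  # metabolite -> max rate
    secretions: dict[str, float] = field(default_factory=dict)
    biomass: dict[str, float] = field(default_factory=dict)
    biomass_ub: float = 1000.0
    recycle_dG0: dict[str, float] = field(default_factory=dict)
    pools: dict[str, tuple[str, str]] = field(default_factory=lambda: dict(TOY_POOLS))
    c_min: float = 1e-6
    c_max: float = 0.02
    seed: int | None = None

    def validate(self) -> None:
        if not self.steps:
            raise ConfigurationError("toy spec needs at least one step")
        if not self.biomass:
            raise ConfigurationError("toy spec needs a biomass sink")
        for step in self.steps:
            if step.pool is not None and step.pool not in self.pools:
                raise ConfigurationError(
                    f"step {step.id!r} uses undefined pool {step.pool!r}"
                )
            if step.mode not in ("reduce", "oxidize"):
                raise ConfigurationError(f"step {step.id!r}: bad mode {step.mode!r}")


def generate_toy(
    spec: ToyNetworkSpec,
) -> tuple[MetabolicModel, ThermoAnnotation, CofactorSpec]:
    """Build a deterministic toy model from its spec."""
    spec.validate()
    reactions: dict[str, Reaction] = {}
    dG0: dict[str, float] = {}
    met_ids: set[str] = set()

    for met, ub in spec.uptakes.items():
        rid = f"EX_{met}_in"
        reactions[rid] = Reaction(rid, {met: 1.0}, 0.0, ub)
        met_ids.add(met)
    for met, ub in spec.secretions.items():
        rid = f"EX_{met}_out"
        reactions[rid] = Reaction(rid, {met: -1.0}, 0.0, ub)
        met_ids.add(met)

    pools_used: set[str] = set()
    for step in spec.steps:
        stoich = {step.substrate: -1.0, step.product: 1.0}
        if step.pool is not None:
            ox, red = spec.pools[step.pool]
            src, dst = (ox, red) if step.mode == "reduce" else (red, ox)
            stoich[src] = stoich.get(src, 0.0) - step.cof_coef
            stoich[dst] = stoich.get(dst, 0.0) + step.cof_coef
            pools_used.add(step.pool)
        lb = -step.ub if step.reversible else 0.0
        reactions[step.id] = Reaction(step.id, stoich, lb, step.ub)
        dG0[step.id] = step.dG0
        met_ids |= set(stoich)

    for pool, g in spec.recycle_dG0.items():
        if pool not in spec.pools:
            raise ConfigurationError(f"recycle for undefined pool {pool!r}")
        ox, red = spec.pools[pool]
        rid = f"RECYCLE_{pool}"
        reactions[rid] = Reaction(rid, {red: -1.0, ox: 1.0}, 0.0, 1000.0)
        dG0[rid] = g
        met_ids |= {ox, red}
        pools_used.add(pool)

    reactions["BIOMASS"] = Reaction("BIOMASS", dict(spec.biomass), 0.0, spec.biomass_ub)
    met_ids |= set(spec.biomass)

    # pool species always present so reconfiguration works on redox-free toys
    for ox, red in spec.pools.values():
        met_ids |= {ox, red}

    model = MetabolicModel(
        metabolites={m: Metabolite(m, compartment="c") for m in sorted(met_ids)},
        reactions=reactions,
        objective_reaction_id="BIOMASS",
    )
    model.validate()
    thermo = ThermoAnnotation(
        dG0=dG0,
        dG0_source_tag={rid: "computed" for rid in dG0},
        default_c_min=spec.c_min,
        default_c_max=spec.c_max,
    )
    cof = CofactorSpec(pools={p: spec.pools[p] for p in sorted(spec.pools)})
    return model, thermo, cof


def linear_chain(
    n_steps: int, dG0s: list[float] | None = None, uptake_ub: float = 10.0
) -> tuple[MetabolicModel, ThermoAnnotation, CofactorSpec]:
    """Unbranched pathway M0 -> M1 -> ... -> Mn with per-step dG0 values.

    All chain metabolites share the standard concentration range, so with
    all dG0 = 0 the MDF equals ``RT ln(c_max / c_min) / n_steps``.
    """
    dG0s = dG0s if dG0s is not None else [0.0] * n_steps
    if len(dG0s) != n_steps:
        raise ConfigurationError("need one dG0 per step")
    steps = [
        StepSpec(f"S{i+1}", f"M{i}", f"M{i+1}", dG0=dG0s[i]) for i in range(n_steps)
    ]
    spec = ToyNetworkSpec(
        steps=steps,
        uptakes={"M0": uptake_ub},
        biomass={f"M{n_steps}": -1.0},
    )
    return generate_toy(spec)


def redox_fixture(
    nadph_demand: float = 0.2,
    cat_dG0: float = 0.0,
    ana_dG0: float = 0.0,
) -> tuple[MetabolicModel, ThermoAnnotation, CofactorSpec]:
    """Catabolic/anabolic fixture exercising both cofactor pools.

    An NAD+-reducing catabolic step (CAT) and an NADPH-consuming anabolic
    step (ANA) both have to run to make biomass, so at a high MDF the
    optimizer must keep the NAD pool oxidized and the NADP pool reduced --
    the ratio quotient ([NADH]/[NAD+]) / ([NADPH]/[NADP+]) stays below 1.
    The oxidative branch (PPP) supplies NADPH at a 'comfortable' dG0 and
    an overflow valve (secretion of b) decouples its flux from the
    anabolic demand.
    """
    steps = [
        StepSpec("CAT", "a", "d", dG0=cat_dG0, pool="NAD", mode="reduce"),
        StepSpec("GLY", "a", "b", dG0=-5.0),
        StepSpec("PPP", "a", "b", dG0=-30.0, pool="NADP", mode="reduce"),
        StepSpec("ANA", "b", "c", dG0=ana_dG0, pool="NADP", mode="oxidize"),
    ]
    spec = ToyNetworkSpec(
        steps=steps,
        uptakes={"a": 10.0},
        secretions={"b": 1000.0},
        biomass={"c": -1.0, "d": -1.0, "nadph": -nadph_demand, "nadp": nadph_demand},
        recycle_dG0={"NAD": -60.0},
    )
    return generate_toy(spec)


def random_toy(seed: int) -> tuple[MetabolicModel, ThermoAnnotation, CofactorSpec]:
    """Seeded random small network (guaranteed oracle-enumerable).

    A 2-3 step chain whose steps draw dG0 uniformly from [-12, 6] kJ/mol;
    with probability ~1/2 one step is redox-coupled (plus a regeneration
    reaction), with probability ~1/2 a parallel bypass of the chain is
    added, and one interior step may be reversible. The demanded sink flux
    always has a stoichiometric route by construction.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 4))
    steps = []
    redox_at = int(rng.integers(0, n)) if rng.random() < 0.5 else -1
    rev_at = int(rng.integers(0, n)) if rng.random() < 0.3 else -1
    for i in range(n):
        dg = float(np.round(rng.uniform(-12.0, 6.0), 2))
        steps.append(
            StepSpec(
                f"S{i+1}",
                f"M{i}",
                f"M{i+1}",
                dG0=dg,
                pool="NAD" if i == redox_at else None,
                mode="reduce",
                reversible=(i == rev_at),
            )
        )
    if rng.random() < 0.5:
        steps.append(
            StepSpec("BYPASS", "M0", f"M{n}", dG0=float(np.round(rng.uniform(-15.0, 3.0), 2)))
        )
    spec = ToyNetworkSpec(
        steps=steps,
        uptakes={"M0": 10.0},
        biomass={f"M{n}": -1.0},
        recycle_dG0={"NAD": -35.0} if redox_at >= 0 else {},
        seed=seed,
    )
    return generate_toy(spec)
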