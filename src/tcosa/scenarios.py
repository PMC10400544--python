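"""Cofactor-specificity scenarios, growth-rate sweeps and swap analyses.

Four specificity scenarios are supported for a cofactor-expanded model:

* ``wild_type`` — each redox reaction keeps its native pool; the swapped
  variant is blocked.
* ``single_pool`` — every redox reaction uses the first pool; the growth
  reaction's second-pool cofactor demand is transferred to the first pool
  and the remaining dual-cofactor reactions (which would couple a pool to
  itself) are blocked.
* ``flexible`` — both variants stay open; the at-most-one-active MILP
  constraint alone arbitrates.
* ``random`` — a sampled specificity, with either a free pool size (fair
  coin per reaction) or a fixed pool size (native NAD/NADP counts
  preserved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .milp import (
    FluxConstraints,
    MdfSolution,
    MilpConfig,
    default_submdf_subset,
    solve_at_fixed_optimum,
    solve_mdf,
    solve_min_swaps,
    solve_submdf,
)
from .model import ConfigurationError, TcosaModel

__all__ = [
    "SpecificityAssignment",
    "GrowthRateGrid",
    "SwapResult",
    "wild_type_assignment",
    "single_pool_assignment",
    "flexible_assignment",
    "apply_scenario",
    "max_growth",
    "growth_grid",
    "sample_random_specificity",
    "solve_objective",
    "single_swap_scan",
    "min_swaps_to_target",
    "active_reaction_census",
    "compare_three_cofactor",
]


@dataclass
class SpecificityAssignment:
    """Per-original-reaction cofactor choice for one scenario instance."""

    choices: dict[str, str]  # original reaction id -> pool name | flexible | blocked
    scenario: str = "wild_type"  # wild_type | single_pool | flexible | random
    seed: int | None = None
    pool_mode: str | None = None  # free | fixed (random scenario only)


@dataclass
class GrowthRateGrid:
    """Descending growth-rate set points for a sweep.

    Starts at 99% of the maximal growth rate, steps down by ``step`` and
    appends the ``floor`` as smallest considered rate; values rounded to
    3 decimals.
    """

    mu_max: float
    set_points: list[float]
    step: float = 0.05
    floor: float = 0.05


@dataclass
class SwapResult:
    objective: str  # MDF | SubMDF
    baseline: dict[float, float] = field(default_factory=dict)
    deltas: dict[str, dict[float, float]] = field(default_factory=dict)
    infeasible_swaps: set[str] = field(default_factory=set)
    minimal_swap_count: int | None = None
    minimal_swap_set: set[str] = field(default_factory=set)


def wild_type_assignment(tcosa: TcosaModel) -> SpecificityAssignment:
    """Native pool of each duplicated reaction, read from provenance."""
    choices: dict[str, str] = {}
    for orig in tcosa.duplicated_originals():
        native = {
            tcosa.provenance[m].pool
            for m in tcosa.variant_groups[orig]
            if not tcosa.provenance[m].is_variant and tcosa.provenance[m].pool
        }
        if len(native) != 1:
            raise ConfigurationError(f"ambiguous native pool for {orig!r}")
        choices[orig] = native.pop()
    return SpecificityAssignment(choices, scenario="wild_type")


def single_pool_assignment(tcosa: TcosaModel, pool: str = "NAD") -> SpecificityAssignment:
    return SpecificityAssignment(
        {orig: pool for orig in tcosa.duplicated_originals()}, scenario="single_pool"
    )


def flexible_assignment(tcosa: TcosaModel) -> SpecificityAssignment:
    return SpecificityAssignment(
        {orig: "flexible" for orig in tcosa.duplicated_originals()},
        scenario="flexible",
    )


def apply_scenario(tcosa: TcosaModel, assignment: SpecificityAssignment) -> TcosaModel:
    """Return a copy of the model with variant bounds blocked per scenario."""
    out = tcosa.copy()
    known = set(tcosa.variant_groups)
    for orig in assignment.choices:
        if orig not in known:
            raise ConfigurationError(f"assignment references unknown reaction {orig!r}")
    for orig, choice in assignment.choices.items():
        members = out.variant_groups[orig]
        if choice == "flexible":
            continue
        for rid in members:
            pool = out.provenance[rid].pool
            if pool is None:
                continue
            if choice == "blocked" or pool != choice:
                rxn = out.network.reactions[rid]
                rxn.lb = 0.0
                rxn.ub = 0.0

    if assignment.scenario == "single_pool":
        _rewrite_single_pool_duals(out, assignment)
    return out


def _rewrite_single_pool_duals(out: TcosaModel, assignment: SpecificityAssignment) -> None:
    """Transfer the growth reaction's second-pool demand to the kept pool
    and block the other dual-cofactor reactions (transhydrogenase-like
    reactions would couple the single pool to itself)."""
    kept = next(iter(set(assignment.choices.values()) - {"flexible", "blocked"}), "NAD")
    kept_ox, kept_red = out.cofactors.pools[kept]
    obj = out.network.objective_reaction_id
    rxn = out.network.reactions[obj]
    for pool, (ox, red) in out.cofactors.pools.items():
        if pool == kept:
            continue
        for src, dst in ((ox, kept_ox), (red, kept_red)):
            if src in rxn.stoich:
                rxn.stoich[dst] = rxn.stoich.get(dst, 0.0) + rxn.stoich.pop(src)
                if rxn.stoich[dst] == 0.0:
                    del rxn.stoich[dst]
    for rid in out.dual_cofactor_reaction_ids:
        if rid != obj and rid in out.network.reactions:
            blocked = out.network.reactions[rid]
            blocked.lb = 0.0
            blocked.ub = 0.0


def max_growth(tcosa: TcosaModel, assignment: SpecificityAssignment | None = None) -> float:
    """LP-maximal growth rate, thermodynamic constraints excluded (FBA)."""
    model = apply_scenario(tcosa, assignment).network if assignment else tcosa.network
    rids = list(model.reactions)
    idx = {rid: i for i, rid in enumerate(rids)}
    bounds = [
        (r.lb, r.ub if math.isfinite(r.ub) else 1000.0) for r in model.reactions.values()
    ]
    A_eq, b_eq = [], []
    for met in model.internal_metabolites():
        row = np.zeros(len(rids))
        touched = False
        for rid, rxn in model.reactions.items():
            coef = rxn.stoich.get(met)
            if coef:
                row[idx[rid]] = coef
                touched = True
        if touched:
            A_eq.append(row)
            b_eq.append(0.0)
    c = np.zeros(len(rids))
    c[idx[model.objective_reaction_id]] = -1.0
    res = linprog(
        c,
        A_eq=np.array(A_eq) if A_eq else None,
        b_eq=np.array(b_eq) if b_eq else None,
        bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        raise RuntimeError(f"FBA infeasible (status {res.status})")
    return float(-res.fun)


def growth_grid(mu_max: float, step: float = 0.05, floor: float = 0.05) -> GrowthRateGrid:
    """Descending set points: 99% of mu_max, stepped down by ``step``, with
    the ``floor`` appended as smallest considered growth rate."""
    start = round(0.99 * mu_max, 3)
    if mu_max <= floor:
        return GrowthRateGrid(mu_max, [start], step, floor)
    points: list[float] = []
    k = 0
    while True:
        val = round(start - k * step, 3)
        if val < floor:
            break
        points.append(val)
        k += 1
    if not points or points[-1] != round(floor, 3):
        points.append(round(floor, 3))
    return GrowthRateGrid(mu_max, points, step, floor)


def sample_random_specificity(
    tcosa: TcosaModel,
    n_samples: int,
    seed: int,
    pool_mode: str = "free",
) -> list[SpecificityAssignment]:
    """Random pool choices for every duplicated reaction.

    ``free`` mode flips an independent fair coin per reaction; ``fixed``
    mode draws uniformly among assignments preserving the wild type's
    per-pool counts. Deterministic for a given seed.
    """
    pools = sorted(_two_native_pools(tcosa))
    originals = sorted(tcosa.duplicated_originals())
    rng = np.random.default_rng(seed)
    wild = wild_type_assignment(tcosa)
    out: list[SpecificityAssignment] = []
    if pool_mode == "fixed":
        counts = {p: sum(1 for c in wild.choices.values() if c == p) for p in pools}
        if sum(counts.values()) != len(originals):
            raise ConfigurationError("pool counts do not cover all duplicated reactions")
    for _ in range(n_samples):
        if pool_mode == "free":
            picks = rng.integers(0, len(pools), size=len(originals))
            choices = {o: pools[int(p)] for o, p in zip(originals, picks)}
        elif pool_mode == "fixed":
            labels = [p for p in pools for _ in range(counts[p])]
            perm = rng.permutation(len(labels))
            choices = {o: labels[int(j)] for o, j in zip(originals, perm)}
        else:
            raise ConfigurationError(f"unknown pool_mode {pool_mode!r}")
        out.append(
            SpecificityAssignment(choices, scenario="random", seed=seed, pool_mode=pool_mode)
        )
    return out


def _two_native_pools(tcosa: TcosaModel) -> set[str]:
    return {
        prov.pool
        for prov in tcosa.provenance.values()
        if prov.pool is not None and not prov.is_variant
    } or set(tcosa.cofactors.pools)


def solve_objective(
    tcosa: TcosaModel,
    assignment: SpecificityAssignment,
    growth_rate: float,
    objective: str = "MDF",
    config: MilpConfig | None = None,
) -> MdfSolution:
    """(Sub)MDF of one scenario at one growth-rate set point."""
    applied = apply_scenario(tcosa, assignment)
    cons = FluxConstraints(growth_min=growth_rate)
    if objective.upper() == "MDF":
        return solve_mdf(applied, cons, config)
    if objective.upper() == "SUBMDF":
        return solve_submdf(applied, None, cons, config)
    raise ConfigurationError(f"unknown objective {objective!r}")


def single_swap_scan(
    tcosa: TcosaModel,
    wildtype: SpecificityAssignment,
    grid: GrowthRateGrid,
    objective: str = "MDF",
    config: MilpConfig | None = None,
) -> SwapResult:
    """Flip each duplicated reaction's specificity separately and record
    the resulting change of the (Sub)MDF per growth-rate set point.

    Swaps that make the demanded growth stoichiometrically infeasible at
    every set point are flagged and excluded from the delta table.
    """
    config = config or MilpConfig()
    result = SwapResult(objective=objective)
    for mu in grid.set_points:
        sol = solve_objective(tcosa, wildtype, mu, objective, config)
        result.baseline[mu] = _value(sol, objective)

    pools = sorted(_two_native_pools(tcosa))
    for orig in sorted(wildtype.choices):
        native = wildtype.choices[orig]
        others = [p for p in pools if p != native]
        if len(others) != 1:
            continue
        flipped = SpecificityAssignment(
            {**wildtype.choices, orig: others[0]}, scenario="wild_type"
        )
        any_feasible = False
        per_mu: dict[float, float] = {}
        for mu in grid.set_points:
            sol = solve_objective(tcosa, flipped, mu, objective, config)
            if not sol.feasible:
                continue
            any_feasible = True
            per_mu[mu] = _value(sol, objective) - result.baseline[mu]
        if any_feasible:
            result.deltas[orig] = per_mu
        else:
            result.infeasible_swaps.add(orig)
    return result


def _value(sol: MdfSolution, objective: str) -> float:
    if not sol.feasible:
        return math.nan
    return sol.B if objective.upper() == "MDF" else sol.B_sub


def min_swaps_to_target(
    tcosa: TcosaModel,
    wildtype: SpecificityAssignment,
    growth_rate: float,
    B_target: float | None = None,
    B_sub_target: float | None = None,
    config: MilpConfig | None = None,
) -> tuple[int, set[str]]:
    """Minimum number of cofactor swaps in the wild type to reach the
    flexible-scenario (Sub)MDF optimum at the given growth rate."""
    wild_pool = {
        orig: pool
        for orig, pool in wildtype.choices.items()
        if pool not in ("flexible", "blocked")
    }
    cons = FluxConstraints(growth_min=growth_rate)
    return solve_min_swaps(
        tcosa,
        wild_pool,
        B_target=B_target,
        B_sub_target=B_sub_target,
        constraints=cons,
        config=config,
    )


def active_reaction_census(
    tcosa: TcosaModel,
    assignment: SpecificityAssignment,
    grid: GrowthRateGrid,
    objective: str = "MDF",
    config: MilpConfig | None = None,
) -> set[str]:
    """Redox reactions able to carry flux in *some* optimal solution.

    For each set point the (Sub)MDF optimum is computed and re-imposed;
    each open cofactor-variant reaction is then individually maximized.
    A reaction whose maximal flux exceeds the activity threshold in any
    set point enters the census (multiplicity of optima is thereby
    accounted for). Returns derived reaction ids.
    """
    config = config or MilpConfig()
    applied = apply_scenario(tcosa, assignment)
    redox_open = [
        rid
        for rid, prov in applied.provenance.items()
        if prov.pool is not None and applied.network.reactions[rid].ub > 0
    ]
    census: set[str] = set()
    for mu in grid.set_points:
        cons = FluxConstraints(growth_min=mu)
        if objective.upper() == "MDF":
            opt = solve_mdf(applied, cons, config)
            targets = {"B_target": opt.B}
        else:
            opt = solve_submdf(applied, None, cons, config)
            targets = {"B_sub_target": opt.B_sub}
        if not opt.feasible:
            continue
        for rid in redox_open:
            if rid in census:
                continue
            sol = solve_at_fixed_optimum(
                applied,
                {rid: ("flux", 1.0)},
                constraints=cons,
                config=config,
                maximize=True,
                **targets,
            )
            if sol.objective_value is not None and sol.objective_value > config.eps_active:
                census.add(rid)
    return census


def compare_three_cofactor(
    tcosa_two_pool: TcosaModel,
    tcosa_three_by_label: dict[str, TcosaModel],
    grid: GrowthRateGrid,
    objective: str = "MDF",
    config: MilpConfig | None = None,
) -> pd.DataFrame:
    """Flexible-specificity (Sub)MDF of the two-pool model versus each
    three-pool variant, per growth-rate set point, with deltas."""
    config = config or MilpConfig()
    rows = []
    for mu in grid.set_points:
        base = solve_objective(
            tcosa_two_pool, flexible_assignment(tcosa_two_pool), mu, objective, config
        )
        base_val = _value(base, objective)
        rows.append(
            {"growth_rate": mu, "model": "two_pool", "objective": objective,
             "value_kJ_mol": base_val, "delta_vs_two_pool": 0.0}
        )
        for label, t3 in tcosa_three_by_label.items():
            sol = solve_objective(t3, flexible_assignment(t3), mu, objective, config)
            val = _value(sol, objective)
            rows.append(
                {"growth_rate": mu, "model": label, "objective": objective,
                 "value_kJ_mol": val, "delta_vs_two_pool": val - base_val}
            )
    return pd.DataFrame(rows)
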