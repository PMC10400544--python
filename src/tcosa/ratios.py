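"""Variability of the redox cofactor concentration-ratio quotient.

At a fixed (Sub)MDF optimum, the feasible extremes of

    rho = ln( ([NADH]/[NAD+]) / ([NADPH]/[NADP+]) )
        = x_NADH + x_NADP+ - x_NADPH - x_NAD+

are found by two MILPs (maximize and minimize rho over fluxes, activity
indicators and log concentrations, with the previously found optimum
re-imposed). A quotient below 1 reproduces the physiological situation
where the NAD pool is kept far more oxidized than the NADP pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .milp import FluxConstraints, MilpConfig, solve_at_fixed_optimum
from .model import ConfigurationError, TcosaModel
from .scenarios import SpecificityAssignment, apply_scenario

__all__ = ["RatioRange", "ratio_range"]


@dataclass
class RatioRange:
    rho_min: float
    rho_max: float
    objective: str
    fixed_value: float
    growth_rate: float

    @property
    def ratio_min(self) -> float:
        return math.exp(self.rho_min)

    @property
    def ratio_max(self) -> float:
        return math.exp(self.rho_max)


def _rho_objective(tcosa: TcosaModel, numerator_pool: str, denominator_pool: str):
    pools = tcosa.cofactors.pools
    for p in (numerator_pool, denominator_pool):
        if p not in pools:
            raise ConfigurationError(f"unknown cofactor pool {p!r}")
    num_ox, num_red = pools[numerator_pool]
    den_ox, den_red = pools[denominator_pool]
    return {
        num_red: ("logc", 1.0),
        den_ox: ("logc", 1.0),
        num_ox: ("logc", -1.0),
        den_red: ("logc", -1.0),
    }


def ratio_range(
    tcosa: TcosaModel,
    assignment: SpecificityAssignment,
    growth_rate: float,
    fixed_value: float,
    objective: str = "MDF",
    numerator_pool: str = "NAD",
    denominator_pool: str = "NADP",
    config: MilpConfig | None = None,
) -> RatioRange:
    """Feasible extremes of the reduced/oxidized ratio quotient.

    ``fixed_value`` is the previously computed optimal MDF (or SubMDF when
    ``objective="SubMDF"``) for the same scenario and growth rate; it is
    re-imposed as a lower bound at the configured equality band. Only the
    objective value is fixed -- fluxes and activity indicators may differ
    between the two extreme solutions.
    """
    config = config or MilpConfig()
    applied = apply_scenario(tcosa, assignment)
    cons = FluxConstraints(growth_min=growth_rate)
    obj = _rho_objective(applied, numerator_pool, denominator_pool)
    targets = (
        {"B_sub_target": fixed_value}
        if objective.upper() == "SUBMDF"
        else {"B_target": fixed_value}
    )
    hi = solve_at_fixed_optimum(
        applied, obj, constraints=cons, config=config, maximize=True, **targets
    )
    lo = solve_at_fixed_optimum(
        applied, obj, constraints=cons, config=config, maximize=False, **targets
    )
    return RatioRange(
        rho_min=float(lo.objective_value),
        rho_max=float(hi.objective_value),
        objective=objective,
        fixed_value=fixed_value,
        growth_rate=growth_rate,
    )
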