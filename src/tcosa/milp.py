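"""Max-min driving force (MDF) mixed-integer linear programs.

Implements the network-embedded MDF formulation: given an irreversible
stoichiometric network with standard reaction Gibbs energies and metabolite
concentration ranges, find a steady-state flux distribution, log
concentrations x and binary activity indicators z maximizing the bound B
such that every active thermo-constrained reaction has driving force

    f_i = -dG0_i - RT * nu_i^T x  >=  B,

with mass balance N r = 0, flux bounds, big-M deactivation of inactive
reactions and at-most-one-active constraints within each group of reaction
variants derived from the same original reaction. The SubMDF variant
maximizes the minimum driving force over a chosen reaction subset while
the rest of the network only has to clear a small feasibility floor.

All programs are solved with the HiGHS solver through
:func:`scipy.optimize.milp`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .model import TcosaModel

__all__ = [
    "MilpConfig",
    "FluxConstraints",
    "MdfSolution",
    "StoichiometricInfeasibility",
    "driving_force",
    "compute_big_M",
    "solve_mdf",
    "solve_submdf",
    "solve_at_fixed_optimum",
    "solve_min_relaxation",
    "solve_min_swaps",
    "default_submdf_subset",
]


class StoichiometricInfeasibility(RuntimeError):
    """No flux distribution satisfies the stoichiometric constraints."""


@dataclass
class MilpConfig:
    """Solver configuration.

    ``big_M`` is either the string ``"auto"`` (bound computed from the dG0
    values and concentration ranges, guaranteed to exceed any attainable
    driving force) or a fixed value in kJ/mol. ``eps_active`` is the flux
    threshold above which a reaction counts as active in reported solution
    sets. ``B_min`` is the network-wide feasibility floor used by SubMDF
    (kJ/mol). ``equality_band`` is the tolerance used when an optimum is
    re-imposed as a constraint in follow-up problems.
    """

    big_M: float | str = "auto"
    solver: str = "highs"
    feasibility_tol: float = 1e-9
    integrality_tol: float = 1e-9
    eps_active: float = 1e-6
    B_min: float = 0.1
    equality_band: float = 1e-3
    default_flux_cap: float = 1000.0

    def __post_init__(self):
        if self.eps_active <= 0:
            raise ValueError("eps_active must be positive")
        if self.B_min <= 0:
            raise ValueError("B_min must be positive")


@dataclass
class FluxConstraints:
    """Extra flux-space constraints for a solve.

    ``extra`` holds arbitrary linear rows over reaction fluxes as
    ``(coefficients-by-reaction-id, lower, upper)`` -- the generic
    D r <= d hook.
    """

    growth_min: float | None = None
    fixed_fluxes: dict[str, float] = field(default_factory=dict)
    blocked: set[str] = field(default_factory=set)
    extra: list[tuple[dict[str, float], float, float]] = field(default_factory=list)


@dataclass
class MdfSolution:
    B: float
    status: str
    B_sub: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)
    log_concentrations: dict[str, float] = field(default_factory=dict)
    driving_forces: dict[str, float] = field(default_factory=dict)
    z: dict[str, int] = field(default_factory=dict)
    active_reactions: set[str] = field(default_factory=set)
    objective_value: float | None = None

    @property
    def feasible(self) -> bool:
        return self.status == "optimal"


def driving_force(reaction_id: str, x: dict[str, float], tcosa: TcosaModel) -> float:
    """f_i = -dG0_i - RT * sum_m nu_mi x_m for a thermo-active reaction.

    ``x`` maps metabolite ids to log concentrations; fixed-unit species
    (x pinned to 0) and metabolites absent from ``x`` contribute nothing.
    External metabolites do contribute: the driving force uses the extended
    stoichiometry.
    """
    if not tcosa.thermo_active.get(reaction_id, False):
        raise ValueError(f"reaction {reaction_id!r} is not thermo-active")
    rxn = tcosa.network.reactions[reaction_id]
    RT = tcosa.thermo.RT
    term = sum(
        coef * x.get(met, 0.0)
        for met, coef in rxn.stoich.items()
        if met not in tcosa.thermo.fixed_unit_species
    )
    return -tcosa.thermo.dG0[reaction_id] - RT * term


def _log_bound_magnitude(tcosa: TcosaModel, met: str) -> float:
    lo, hi = tcosa.thermo.conc_bounds(met)
    return max(abs(math.log(lo)), abs(math.log(hi)))


def compute_big_M(tcosa: TcosaModel, config: MilpConfig) -> float:
    """A constant provably above the maximal attainable driving force."""
    if config.big_M != "auto":
        return float(config.big_M)
    RT = tcosa.thermo.RT
    best = 0.0
    for rid, active in tcosa.thermo_active.items():
        if not active:
            continue
        rxn = tcosa.network.reactions[rid]
        bound = -tcosa.thermo.dG0[rid] + RT * sum(
            abs(coef) * _log_bound_magnitude(tcosa, met)
            for met, coef in rxn.stoich.items()
        )
        best = max(best, bound)
    return best + 1.0


def _force_magnitude_bound(tcosa: TcosaModel) -> float:
    """Bound on |f_i| over all thermo-active reactions (for the B range)."""
    RT = tcosa.thermo.RT
    best = 1.0
    for rid, active in tcosa.thermo_active.items():
        if not active:
            continue
        rxn = tcosa.network.reactions[rid]
        bound = abs(tcosa.thermo.dG0[rid]) + RT * sum(
            abs(coef) * _log_bound_magnitude(tcosa, met)
            for met, coef in rxn.stoich.items()
        )
        best = max(best, bound)
    return best + 1.0


class _Builder:
    """Assembles the shared MDF MILP skeleton.

    Variable blocks: one flux per reaction, one log concentration per
    non-fixed metabolite, one binary per reaction that is thermo-active or
    belongs to a multi-member variant group, the bound variable B and,
    in SubMDF mode, B_sub.
    """

    def __init__(
        self,
        tcosa: TcosaModel,
        config: MilpConfig,
        constraints: FluxConstraints | None = None,
        submdf_subset: set[str] | None = None,
        relaxable: bool = False,
    ):
        self.tcosa = tcosa
        self.config = config
        self.constraints = constraints or FluxConstraints()
        self.relaxable = relaxable
        self.relax_vars: dict[str, int] = {}
        self.M = compute_big_M(tcosa, config)
        self.B_lo = -_force_magnitude_bound(tcosa)

        self.lb: list[float] = []
        self.ub: list[float] = []
        self.integrality: list[int] = []
        self.rows: list[dict[int, float]] = []
        self.row_lb: list[float] = []
        self.row_ub: list[float] = []

        net = tcosa.network
        thermo = tcosa.thermo

        self.r: dict[str, int] = {}
        for rid, rxn in net.reactions.items():
            cap = rxn.ub if math.isfinite(rxn.ub) else config.default_flux_cap
            self.r[rid] = self._add_var(rxn.lb, cap)

        self.x: dict[str, int] = {}
        for met in net.metabolites:
            if met in thermo.fixed_unit_species:
                continue
            lo, hi = thermo.conc_bounds(met)
            self.x[met] = self._add_var(math.log(lo), math.log(hi))

        needs_z = {rid for rid, act in tcosa.thermo_active.items() if act}
        for members in tcosa.variant_groups.values():
            if len(members) >= 2:
                needs_z |= set(members)
        self.z: dict[str, int] = {}
        for rid in net.reactions:
            if rid in needs_z:
                self.z[rid] = self._add_var(0, 1, integer=True)

        self.B = self._add_var(self.B_lo, self.M)
        self.B_sub: int | None = None
        self.submdf_subset = submdf_subset
        if submdf_subset is not None:
            self.B_sub = self._add_var(self.B_lo, self.M)

        self._build_core()

    # -- variable/constraint plumbing -----------------------------------
    def _add_var(self, lo: float, hi: float, integer: bool = False) -> int:
        self.lb.append(lo)
        self.ub.append(hi)
        self.integrality.append(1 if integer else 0)
        return len(self.lb) - 1

    def add_row(self, coeffs: dict[int, float], lo: float, hi: float) -> None:
        self.rows.append(coeffs)
        self.row_lb.append(lo)
        self.row_ub.append(hi)

    # -- core constraints ------------------------------------------------
    def _build_core(self) -> None:
        net = self.tcosa.network
        RT = self.tcosa.thermo.RT
        M = self.M

        balance: dict[str, dict[int, float]] = {
            m: {} for m in net.internal_metabolites()
        }
        for rid, rxn in net.reactions.items():
            col = self.r[rid]
            for met, coef in rxn.stoich.items():
                if met in balance:
                    balance[met][col] = balance[met].get(col, 0.0) + coef
        for met, coeffs in balance.items():
            if coeffs:
                self.add_row(coeffs, 0.0, 0.0)

        for rid, zi in self.z.items():
            cap = self.ub[self.r[rid]]
            self.add_row({self.r[rid]: 1.0, zi: -cap}, -math.inf, 0.0)

        for rid, active in self.tcosa.thermo_active.items():
            if not active:
                continue
            self._driving_force_row(rid, self.B, RT, M)

        if self.submdf_subset is not None:
            for rid in self.submdf_subset:
                if self.tcosa.thermo_active.get(rid, False):
                    self._driving_force_row(rid, self.B_sub, RT, M)

        for members in self.tcosa.variant_groups.values():
            zs = [self.z[m] for m in members if m in self.z]
            if len(zs) >= 2:
                self.add_row({zi: 1.0 for zi in zs}, -math.inf, 1.0)

        cons = self.constraints
        if cons.growth_min is not None:
            obj = net.objective_reaction_id
            self.add_row({self.r[obj]: 1.0}, cons.growth_min, math.inf)
        for rid, val in cons.fixed_fluxes.items():
            self.add_row({self.r[rid]: 1.0}, val, val)
        for rid in cons.blocked:
            self.add_row({self.r[rid]: 1.0}, 0.0, 0.0)
        for coeffs, lo, hi in cons.extra:
            self.add_row({self.r[rid]: c for rid, c in coeffs.items()}, lo, hi)

    def _driving_force_row(self, rid: str, bound_var: int, RT: float, M: float) -> None:
        # bound + RT * nu^T x + M z_i [- 2M y_i] <= M - dG0_i
        rxn = self.tcosa.network.reactions[rid]
        coeffs: dict[int, float] = {bound_var: 1.0, self.z[rid]: M}
        for met, coef in rxn.stoich.items():
            xm = self.x.get(met)
            if xm is not None:
                coeffs[xm] = coeffs.get(xm, 0.0) + RT * coef
        if self.relaxable and bound_var == self.B:
            yi = self._add_var(0, 1, integer=True)
            self.relax_vars[rid] = yi
            coeffs[yi] = -(2 * M + abs(self.B_lo))
        self.add_row(coeffs, -math.inf, M - self.tcosa.thermo.dG0[rid])

    # -- solve -----------------------------------------------------------
    def solve(self, objective: dict[int, float], maximize: bool = True):
        self._last_maximize = maximize
        n = len(self.lb)
        c = np.zeros(n)
        for idx, coef in objective.items():
            c[idx] = -coef if maximize else coef
        if self.rows:
            data, ri, ci = [], [], []
            for i, coeffs in enumerate(self.rows):
                for j, v in coeffs.items():
                    ri.append(i)
                    ci.append(j)
                    data.append(v)
            A = sparse.csr_matrix((data, (ri, ci)), shape=(len(self.rows), n))
            lc = LinearConstraint(A, np.array(self.row_lb), np.array(self.row_ub))
        else:
            lc = []
        res = milp(
            c,
            constraints=lc,
            integrality=np.array(self.integrality),
            bounds=Bounds(np.array(self.lb), np.array(self.ub)),
            options={"mip_rel_gap": 1e-9, "presolve": True},
        )
        return res

    def extract(self, res) -> MdfSolution:
        status = {0: "optimal", 1: "limit", 2: "infeasible", 3: "unbounded"}.get(
            res.status, "failed"
        )
        if res.x is None:
            return MdfSolution(B=math.nan, status=status)
        xv = res.x
        fluxes = {rid: float(xv[i]) for rid, i in self.r.items()}
        logc = {met: float(xv[i]) for met, i in self.x.items()}
        for met in self.tcosa.thermo.fixed_unit_species:
            if met in self.tcosa.network.metabolites:
                logc[met] = 0.0
        z = {rid: int(round(xv[i])) for rid, i in self.z.items()}
        forces = {
            rid: driving_force(rid, logc, self.tcosa)
            for rid, act in self.tcosa.thermo_active.items()
            if act
        }
        eps = self.config.eps_active
        active = {rid for rid, v in fluxes.items() if v > eps}
        return MdfSolution(
            B=float(xv[self.B]),
            B_sub=float(xv[self.B_sub]) if self.B_sub is not None else None,
            status=status,
            fluxes=fluxes,
            log_concentrations=logc,
            driving_forces=forces,
            z=z,
            active_reactions=active,
            objective_value=(
                float(-res.fun if getattr(self, "_last_maximize", True) else res.fun)
                if res.fun is not None
                else None
            ),
        )


def default_submdf_subset(tcosa: TcosaModel) -> set[str]:
    """All cofactor-variant reactions (the redox subnetwork of interest)."""
    return {
        rid
        for rid, prov in tcosa.provenance.items()
        if prov.pool is not None and rid in tcosa.network.reactions
    }


def solve_mdf(
    tcosa: TcosaModel,
    constraints: FluxConstraints | None = None,
    config: MilpConfig | None = None,
) -> MdfSolution:
    """Maximize the network MDF under the given flux constraints.

    The returned B may be negative: its absolute value then measures the
    distance from thermodynamic feasibility. A status of ``"infeasible"``
    means no flux distribution satisfies the stoichiometric constraints at
    all, which is distinct from a feasible solution with B <= 0.
    """
    config = config or MilpConfig()
    builder = _Builder(tcosa, config, constraints)
    res = builder.solve({builder.B: 1.0}, maximize=True)
    sol = builder.extract(res)
    if sol.feasible:
        _audit_big_M(sol, builder.M)
    return sol


def solve_submdf(
    tcosa: TcosaModel,
    subset: set[str] | None = None,
    constraints: FluxConstraints | None = None,
    config: MilpConfig | None = None,
) -> MdfSolution:
    """Maximize the minimum driving force over ``subset`` while every other
    active reaction clears the feasibility floor ``config.B_min``.

    ``subset`` defaults to all cofactor-variant reactions. Returns a
    solution whose ``B_sub`` is at least the plain MDF of the same
    instance whenever both are feasible.
    """
    config = config or MilpConfig()
    if subset is None:
        subset = default_submdf_subset(tcosa)
    if not subset:
        raise ValueError("SubMDF requires a nonempty reaction subset")
    builder = _Builder(tcosa, config, constraints, submdf_subset=subset)
    builder.add_row({builder.B: 1.0}, config.B_min, math.inf)
    res = builder.solve({builder.B_sub: 1.0}, maximize=True)
    sol = builder.extract(res)
    if sol.feasible:
        _audit_big_M(sol, builder.M)
    return sol


def solve_at_fixed_optimum(
    tcosa: TcosaModel,
    objective: dict[str, tuple[str, float]],
    B_target: float | None = None,
    B_sub_target: float | None = None,
    subset: set[str] | None = None,
    constraints: FluxConstraints | None = None,
    config: MilpConfig | None = None,
    maximize: bool = True,
) -> MdfSolution:
    """Optimize a linear function of fluxes/log-concentrations while the
    previously found (Sub)MDF optimum is re-imposed.

    ``objective`` maps arbitrary keys to ``(kind, coefficient)`` pairs with
    kind ``"flux"`` or ``"logc"``, the key being the reaction/metabolite
    id. The optimum is imposed as a one-sided bound at
    ``target - equality_band`` to avoid MILP equality brittleness.
    """
    config = config or MilpConfig()
    sub = None
    if B_sub_target is not None:
        sub = subset if subset is not None else default_submdf_subset(tcosa)
    builder = _Builder(tcosa, config, constraints, submdf_subset=sub)
    band = config.equality_band
    if B_sub_target is not None:
        builder.add_row({builder.B: 1.0}, config.B_min, math.inf)
        builder.add_row({builder.B_sub: 1.0}, B_sub_target - band, math.inf)
    elif B_target is not None:
        builder.add_row({builder.B: 1.0}, B_target - band, math.inf)
    else:
        raise ValueError("one of B_target or B_sub_target is required")

    obj: dict[int, float] = {}
    for key, (kind, coef) in objective.items():
        if kind == "flux":
            obj[builder.r[key]] = obj.get(builder.r[key], 0.0) + coef
        elif kind == "logc":
            if key in tcosa.thermo.fixed_unit_species:
                continue  # pinned to ln(1) = 0
            obj[builder.x[key]] = obj.get(builder.x[key], 0.0) + coef
        else:
            raise ValueError(f"unknown objective kind {kind!r}")
    res = builder.solve(obj, maximize=maximize)
    sol = builder.extract(res)
    if not sol.feasible:
        raise RuntimeError(
            f"fixed-optimum problem infeasible (status {sol.status}); stale optimum?"
        )
    return sol


def solve_min_relaxation(
    tcosa: TcosaModel,
    demanded_growth: float,
    B_min: float,
    config: MilpConfig | None = None,
) -> set[str]:
    """Minimal set of thermo-active reactions whose driving-force
    constraint must be dropped so that B >= B_min at the demanded growth."""
    config = config or MilpConfig()
    cons = FluxConstraints(growth_min=demanded_growth)
    # Stoichiometric pre-check so the two failure modes stay distinguishable.
    probe = _Builder(tcosa, config, cons)
    feas = probe.solve({}, maximize=False)
    if feas.status == 2:
        raise StoichiometricInfeasibility(
            f"growth {demanded_growth} is stoichiometrically infeasible"
        )

    builder = _Builder(tcosa, config, cons, relaxable=True)
    builder.add_row({builder.B: 1.0}, B_min, math.inf)
    res = builder.solve(
        {yi: 1.0 for yi in builder.relax_vars.values()}, maximize=False
    )
    if res.x is None:
        raise StoichiometricInfeasibility(
            "relaxation MILP infeasible despite stoichiometric feasibility"
        )
    return {rid for rid, yi in builder.relax_vars.items() if round(res.x[yi]) == 1}


def solve_min_swaps(
    tcosa: TcosaModel,
    wildtype_pool: dict[str, str],
    B_target: float | None = None,
    B_sub_target: float | None = None,
    subset: set[str] | None = None,
    constraints: FluxConstraints | None = None,
    config: MilpConfig | None = None,
) -> tuple[int, set[str]]:
    """Minimum number of cofactor swaps for the wild type to reach a
    (Sub)MDF target obtained in the flexible scenario.

    ``wildtype_pool`` maps each duplicated original reaction id to its
    native pool. A single swap binary per original reaction gates the flux
    through all complementary-pool variants (forward and backward copies
    swap together). Returns the swap count and one optimal swap set (ids
    of originals swapped).
    """
    config = config or MilpConfig()
    sub = None
    if B_sub_target is not None:
        sub = subset if subset is not None else default_submdf_subset(tcosa)
    builder = _Builder(tcosa, config, constraints, submdf_subset=sub)
    band = config.equality_band
    if B_sub_target is not None:
        builder.add_row({builder.B: 1.0}, config.B_min, math.inf)
        builder.add_row({builder.B_sub: 1.0}, B_sub_target - band, math.inf)
    elif B_target is not None:
        builder.add_row({builder.B: 1.0}, B_target - band, math.inf)
    else:
        raise ValueError("one of B_target or B_sub_target is required")

    swap_vars: dict[str, int] = {}
    for orig, native in wildtype_pool.items():
        members = tcosa.variant_groups.get(orig, [])
        complementary = [
            rid for rid in members if tcosa.provenance[rid].pool not in (None, native)
        ]
        if not complementary:
            continue
        sk = builder._add_var(0, 1, integer=True)
        swap_vars[orig] = sk
        for rid in complementary:
            cap = builder.ub[builder.r[rid]]
            builder.add_row({builder.r[rid]: 1.0, sk: -cap}, -math.inf, 0.0)

    res = builder.solve({sk: 1.0 for sk in swap_vars.values()}, maximize=False)
    if res.x is None:
        raise RuntimeError(
            "min-swap MILP infeasible: the target should be attainable when it "
            "came from the flexible scenario on the same model"
        )
    chosen = {orig for orig, sk in swap_vars.items() if round(res.x[sk]) == 1}
    return len(chosen), chosen


def _audit_big_M(sol: MdfSolution, M: float) -> None:
    worst = max(sol.driving_forces.values(), default=0.0)
    if worst >= M:
        raise RuntimeError(f"big-M {M} not above attained driving force {worst}")
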