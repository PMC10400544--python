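"""Brute-force reference computation of (Sub)MDF values on toy networks.

Independent of the MILP path: instead of binary activity variables, every
admissible active reaction set is enumerated explicitly. For each candidate
set the existence of a steady-state flux distribution supported on the set
is checked by one LP over fluxes, and the best min-driving-force is found
by a second LP over log concentrations. The maximum over all candidate
sets is the exact (Sub)MDF. Exponential in the reaction count, hence the
hard size guard.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import linprog

from .milp import FluxConstraints, MilpConfig, StoichiometricInfeasibility
from .model import TcosaModel

__all__ = ["brute_force_mdf", "brute_force_submdf", "OracleSizeError"]

_MAX_REACTIONS = 14


class OracleSizeError(ValueError):
    """Model too large for exhaustive enumeration."""


def _support_feasible(
    tcosa: TcosaModel, support: frozenset[str], cons: FluxConstraints, cap: float
) -> bool:
    """Does a flux vector with support inside ``support`` satisfy mass
    balance, bounds and the demanded flux constraints?"""
    net = tcosa.network
    rids = list(net.reactions)
    idx = {rid: i for i, rid in enumerate(rids)}
    bounds = []
    for rid in rids:
        rxn = net.reactions[rid]
        ub = rxn.ub if math.isfinite(rxn.ub) else cap
        if rid in cons.blocked or rid not in support:
            if rxn.lb > 0:
                return False
            bounds.append((0.0, 0.0))
        else:
            bounds.append((rxn.lb, ub))

    A_eq, b_eq = [], []
    for met in net.internal_metabolites():
        row = np.zeros(len(rids))
        touched = False
        for rid, rxn in net.reactions.items():
            coef = rxn.stoich.get(met)
            if coef:
                row[idx[rid]] = coef
                touched = True
        if touched:
            A_eq.append(row)
            b_eq.append(0.0)
    for rid, val in cons.fixed_fluxes.items():
        row = np.zeros(len(rids))
        row[idx[rid]] = 1.0
        A_eq.append(row)
        b_eq.append(val)

    A_ub, b_ub = [], []
    if cons.growth_min is not None:
        row = np.zeros(len(rids))
        row[idx[net.objective_reaction_id]] = -1.0
        A_ub.append(row)
        b_ub.append(-cons.growth_min)
    for coeffs, lo, hi in cons.extra:
        row = np.zeros(len(rids))
        for rid, c in coeffs.items():
            row[idx[rid]] = c
        if math.isfinite(hi):
            A_ub.append(row)
            b_ub.append(hi)
        if math.isfinite(lo):
            A_ub.append(-row)
            b_ub.append(-lo)

    res = linprog(
        np.zeros(len(rids)),
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=np.array(A_eq) if A_eq else None,
        b_eq=np.array(b_eq) if b_eq else None,
        bounds=bounds,
        method="highs",
    )
    return res.status == 0


def _max_min_force(
    tcosa: TcosaModel,
    bounded: list[str],
    floor: list[str] | None = None,
    B_min: float = 0.1,
    cap: float = 1e4,
) -> float | None:
    """LP over log concentrations: maximize B s.t. f_i >= B for
    ``bounded`` reactions and (optionally) f_i >= B_min for ``floor``
    reactions. Returns None if infeasible, +cap if unconstrained."""
    thermo = tcosa.thermo
    mets = [
        m for m in tcosa.network.metabolites if m not in thermo.fixed_unit_species
    ]
    midx = {m: i for i, m in enumerate(mets)}
    n = len(mets) + 1  # x..., B
    RT = thermo.RT

    A_ub, b_ub = [], []

    def force_row(rid: str, rhs_bound: float | None):
        # B - f_i <= 0  <=>  B + RT nu^T x <= -dG0 ; with fixed B_min: RT nu^T x <= -dG0 - B_min
        rxn = tcosa.network.reactions[rid]
        row = np.zeros(n)
        for met, coef in rxn.stoich.items():
            j = midx.get(met)
            if j is not None:
                row[j] += RT * coef
        if rhs_bound is None:
            row[-1] = 1.0
            b = -thermo.dG0[rid]
        else:
            b = -thermo.dG0[rid] - rhs_bound
        A_ub.append(row)
        b_ub.append(b)

    for rid in bounded:
        force_row(rid, None)
    for rid in floor or []:
        force_row(rid, B_min)

    if not A_ub:
        return cap

    bounds = []
    for m in mets:
        lo, hi = thermo.conc_bounds(m)
        bounds.append((math.log(lo), math.log(hi)))
    bounds.append((-cap, cap))

    c = np.zeros(n)
    c[-1] = -1.0  # maximize B
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub), bounds=bounds, method="highs")
    if res.status != 0:
        return None
    return float(res.x[-1]) if bounded else cap


def _enumerate_candidates(tcosa: TcosaModel):
    rids = list(tcosa.network.reactions)
    if len(rids) > _MAX_REACTIONS:
        raise OracleSizeError(
            f"{len(rids)} reactions exceed the enumeration guard ({_MAX_REACTIONS})"
        )
    groups = [set(m) for m in tcosa.variant_groups.values() if len(m) >= 2]
    for r in range(len(rids) + 1):
        for combo in itertools.combinations(rids, r):
            support = frozenset(combo)
            if any(len(support & g) > 1 for g in groups):
                continue
            yield support


def brute_force_mdf(
    tcosa: TcosaModel,
    constraints: FluxConstraints | None = None,
    config: MilpConfig | None = None,
) -> float:
    """Reference MDF by exhaustive enumeration of active reaction sets."""
    config = config or MilpConfig()
    cons = constraints or FluxConstraints()
    best = None
    for support in _enumerate_candidates(tcosa):
        if not _support_feasible(tcosa, support, cons, config.default_flux_cap):
            continue
        ta = [rid for rid in support if tcosa.thermo_active.get(rid, False)]
        B = _max_min_force(tcosa, ta)
        if B is not None and (best is None or B > best):
            best = B
    if best is None:
        raise StoichiometricInfeasibility("no admissible active set is feasible")
    return best


def brute_force_submdf(
    tcosa: TcosaModel,
    subset: set[str],
    constraints: FluxConstraints | None = None,
    config: MilpConfig | None = None,
) -> float | None:
    """Reference SubMDF; ``None`` if no candidate clears the B_min floor."""
    config = config or MilpConfig()
    cons = constraints or FluxConstraints()
    best = None
    for support in _enumerate_candidates(tcosa):
        if not _support_feasible(tcosa, support, cons, config.default_flux_cap):
            continue
        ta = [rid for rid in support if tcosa.thermo_active.get(rid, False)]
        in_sub = [rid for rid in ta if rid in subset]
        out_sub = [rid for rid in ta if rid not in subset]
        # whole network must clear the floor (including subset members)
        floor_ok = _max_min_force(tcosa, ta)
        if floor_ok is None or floor_ok < config.B_min:
            continue
        B_sub = _max_min_force(tcosa, in_sub, floor=ta, B_min=config.B_min)
        if B_sub is not None and (best is None or B_sub > best):
            best = B_sub
    return best
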