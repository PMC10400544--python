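"""Specificity scenarios, growth grids, sampling, swaps and census."""

import itertools
import math

import numpy as np
import pytest

from tcosa import prepare_tcosa_model, redox_fixture
from tcosa.milp import FluxConstraints, MilpConfig
from tcosa.model import CofactorSpec, ConfigurationError
from tcosa.reconfigure import PrepareOptions
from tcosa.scenarios import (
    GrowthRateGrid,
    SpecificityAssignment,
    active_reaction_census,
    apply_scenario,
    compare_three_cofactor,
    flexible_assignment,
    growth_grid,
    max_growth,
    min_swaps_to_target,
    sample_random_specificity,
    single_pool_assignment,
    single_swap_scan,
    solve_objective,
    wild_type_assignment,
)

GRID = GrowthRateGrid(mu_max=5.0, set_points=[1.0])
BAND = 1e-3


# ------------------------------------------------------------ growth grid
@pytest.mark.parametrize(
    "mu_max, n_points, first",
    [(0.877, 18, 0.868), (0.375, 8, 0.371), (0.10, 2, 0.099)],
)
def test_growth_grid_set_point_counts(mu_max, n_points, first):
    grid = growth_grid(mu_max)
    assert len(grid.set_points) == n_points
    assert grid.set_points[0] == first
    assert grid.set_points[-1] == 0.05
    assert grid.set_points == sorted(grid.set_points, reverse=True)


def test_growth_grid_steps_are_uniform_except_final_gap():
    pts = growth_grid(0.877).set_points
    diffs = [round(a - b, 3) for a, b in zip(pts, pts[1:])]
    assert all(d == 0.05 for d in diffs[:-1])
    assert 0 < diffs[-1] <= 0.05


# -------------------------------------------------------------- scenarios
def test_wild_type_blocks_only_the_swapped_variants(fixture_tcosa, fixture_wildtype):
    applied = apply_scenario(fixture_tcosa, fixture_wildtype)
    var = applied.network.reactions["CAT_VARIANT_NADP_TCOSA"]
    orig = applied.network.reactions["CAT_ORIGINAL_NAD_TCOSA"]
    assert (var.lb, var.ub) == (0.0, 0.0)
    assert orig.ub > 0


def test_single_pool_rewrites_biomass_cofactor_demand(fixture_tcosa):
    applied = apply_scenario(fixture_tcosa, single_pool_assignment(fixture_tcosa))
    biomass = applied.network.reactions[applied.network.objective_reaction_id]
    assert "nadph" not in biomass.stoich and "nadp" not in biomass.stoich
    assert biomass.stoich["nadh"] == -0.2 and biomass.stoich["nad"] == 0.2
    # every NADP variant blocked
    for rid, prov in applied.provenance.items():
        if prov.pool == "NADP":
            assert applied.network.reactions[rid].ub == 0.0


def test_flexible_keeps_both_variants_open(fixture_tcosa):
    applied = apply_scenario(fixture_tcosa, flexible_assignment(fixture_tcosa))
    assert applied.network.reactions["CAT_VARIANT_NADP_TCOSA"].ub > 0
    assert applied.network.reactions["CAT_ORIGINAL_NAD_TCOSA"].ub > 0


def test_unknown_reaction_in_assignment_is_rejected(fixture_tcosa):
    bad = SpecificityAssignment({"NOPE": "NAD"})
    with pytest.raises(ConfigurationError):
        apply_scenario(fixture_tcosa, bad)


def test_fba_growth_is_bound_limited(fixture_tcosa, fixture_wildtype):
    # uptake 10, 2.2 substrate per biomass unit -> mu_max = 10 / 2.2
    mu = max_growth(fixture_tcosa, fixture_wildtype)
    assert mu == pytest.approx(10 / 2.2, abs=1e-6)


# ---------------------------------------------------------------- ordering
def test_scenario_ordering_at_every_set_point(fixture_tcosa, fixture_wildtype):
    """single_pool <= wild_type <= flexible, for MDF and SubMDF."""
    for mu in (1.0, 2.0, 4.0):
        for obj in ("MDF", "SubMDF"):
            vals = {}
            for label, a in (
                ("single", single_pool_assignment(fixture_tcosa)),
                ("wild", fixture_wildtype),
                ("flex", flexible_assignment(fixture_tcosa)),
            ):
                sol = solve_objective(fixture_tcosa, a, mu, obj)
                vals[label] = sol.B if obj == "MDF" else sol.B_sub
            assert vals["single"] <= vals["wild"] + BAND
            assert vals["wild"] <= vals["flex"] + BAND


def test_submdf_at_least_mdf_for_every_scenario(fixture_tcosa, fixture_wildtype):
    for a in (fixture_wildtype, flexible_assignment(fixture_tcosa),
              single_pool_assignment(fixture_tcosa)):
        mdf = solve_objective(fixture_tcosa, a, 1.0, "MDF")
        sub = solve_objective(fixture_tcosa, a, 1.0, "SubMDF")
        assert sub.B_sub >= mdf.B - BAND


def test_random_specificities_never_beat_flexible(fixture_tcosa):
    flex = solve_objective(fixture_tcosa, flexible_assignment(fixture_tcosa), 1.0, "MDF").B
    for a in sample_random_specificity(fixture_tcosa, 8, seed=5, pool_mode="free"):
        sol = solve_objective(fixture_tcosa, a, 1.0, "MDF")
        if sol.feasible:
            assert sol.B <= flex + BAND


# ---------------------------------------------------------------- sampling
def test_sampling_is_reproducible_for_a_seed(fixture_tcosa):
    a = sample_random_specificity(fixture_tcosa, 6, seed=11, pool_mode="fixed")
    b = sample_random_specificity(fixture_tcosa, 6, seed=11, pool_mode="fixed")
    assert [x.choices for x in a] == [x.choices for x in b]


def test_fixed_pool_sampling_preserves_wild_type_counts(fixture_tcosa, fixture_wildtype):
    n_nad = sum(1 for v in fixture_wildtype.choices.values() if v == "NAD")
    for a in sample_random_specificity(fixture_tcosa, 20, seed=2, pool_mode="fixed"):
        assert sum(1 for v in a.choices.values() if v == "NAD") == n_nad


def test_free_sampling_is_a_fair_coin(fixture_tcosa):
    samples = sample_random_specificity(fixture_tcosa, 4000, seed=7, pool_mode="free")
    per_rxn = {o: 0 for o in samples[0].choices}
    for a in samples:
        for o, v in a.choices.items():
            per_rxn[o] += v == "NAD"
    for o, count in per_rxn.items():
        assert count / len(samples) == pytest.approx(0.5, abs=0.03)


# ------------------------------------------------------------ single swaps
def test_single_swap_scan_flags_lethal_swaps_and_scores_others(
    fixture_tcosa, fixture_wildtype
):
    res = single_swap_scan(fixture_tcosa, fixture_wildtype, GRID, "MDF")
    # swapping the only NADPH source (or the only NADH sink) kills growth
    assert res.infeasible_swaps == {"PPP", "RECYCLE_NAD"}
    # the surviving swaps move catabolic/anabolic steps onto shared pools
    assert set(res.deltas) == {"CAT", "ANA"}
    for per_mu in res.deltas.values():
        assert all(d <= BAND for d in per_mu.values())


def test_single_swap_delta_matches_direct_resolve(fixture_tcosa, fixture_wildtype):
    res = single_swap_scan(fixture_tcosa, fixture_wildtype, GRID, "MDF")
    flipped = SpecificityAssignment(
        {**fixture_wildtype.choices, "ANA": "NAD"}, scenario="wild_type"
    )
    direct = solve_objective(fixture_tcosa, flipped, 1.0, "MDF").B
    assert res.deltas["ANA"][1.0] == pytest.approx(direct - res.baseline[1.0], abs=1e-6)


# ------------------------------------------------------------- minimal swaps
def _flex_target(t, mu, obj="MDF"):
    sol = solve_objective(t, flexible_assignment(t), mu, obj)
    return sol.B if obj == "MDF" else sol.B_sub


def test_zero_swaps_iff_wild_type_reaches_flexible_optimum(
    fixture_tcosa, fixture_wildtype
):
    target = _flex_target(fixture_tcosa, 1.0)
    wt_val = solve_objective(fixture_tcosa, fixture_wildtype, 1.0, "MDF").B
    count, chosen = min_swaps_to_target(fixture_tcosa, fixture_wildtype, 1.0, B_target=target)
    assert (count == 0) == (abs(wt_val - target) <= BAND)
    assert count == 0 and chosen == set()


def test_minimal_swap_count_verified_by_exhaustive_subset_search(fixture_tcosa):
    """A deliberately mis-specified wild type needs exactly the swaps an
    exhaustive search over all swap subsets finds necessary."""
    wt = wild_type_assignment(fixture_tcosa)
    bad = SpecificityAssignment(
        {**wt.choices, "ANA": "NAD", "CAT": "NADP"}, scenario="wild_type"
    )
    target = _flex_target(fixture_tcosa, 1.0)
    count, chosen = min_swaps_to_target(fixture_tcosa, bad, 1.0, B_target=target)

    def reaches(swapped):
        assign = dict(bad.choices)
        for orig in swapped:
            assign[orig] = "NADP" if assign[orig] == "NAD" else "NAD"
        sol = solve_objective(
            fixture_tcosa, SpecificityAssignment(assign, scenario="wild_type"), 1.0, "MDF"
        )
        return sol.feasible and sol.B >= target - BAND

    brute_best = None
    originals = sorted(bad.choices)
    for r in range(len(originals) + 1):
        if any(reaches(set(c)) for c in itertools.combinations(originals, r)):
            brute_best = r
            break
    assert count == brute_best
    assert reaches(chosen)


# ----------------------------------------------------------------- census
def test_census_contains_the_unique_optimal_pathway(fixture_tcosa, fixture_wildtype):
    census = active_reaction_census(fixture_tcosa, fixture_wildtype, GRID, "MDF")
    sol = solve_objective(fixture_tcosa, fixture_wildtype, 1.0, "MDF")
    redox_active = {
        rid
        for rid in sol.active_reactions
        if fixture_tcosa.provenance.get(rid) and fixture_tcosa.provenance[rid].pool
    }
    assert redox_active <= census


def test_census_detects_interchangeable_alternatives():
    """Two equally good NADPH sources both enter the census."""
    from tcosa.toys import StepSpec, ToyNetworkSpec, generate_toy

    spec = ToyNetworkSpec(
        steps=[
            StepSpec("SRC1", "a", "b", dG0=-30.0, pool="NADP", mode="reduce"),
            StepSpec("SRC2", "a", "b", dG0=-30.0, pool="NADP", mode="reduce"),
            StepSpec("USE", "b", "c", dG0=-5.0, pool="NADP", mode="oxidize"),
        ],
        uptakes={"a": 10.0},
        biomass={"c": -1.0},
    )
    model, thermo, cof = generate_toy(spec)
    t = prepare_tcosa_model(model, thermo, cof)
    census = active_reaction_census(t, wild_type_assignment(t), GRID, "MDF")
    assert {"SRC1_ORIGINAL_NADP_TCOSA", "SRC2_ORIGINAL_NADP_TCOSA"} <= census


# ----------------------------------------------------------- third cofactor
@pytest.fixture(scope="module")
def three_pool_models():
    model, thermo, cof = redox_fixture()
    cof3 = CofactorSpec({**cof.pools, "NADZ": ("nadz", "nadzh")})
    t2 = prepare_tcosa_model(model, thermo, cof)
    by_label = {
        "same_potential": prepare_tcosa_model(
            model, thermo, cof3, PrepareOptions(third_cofactor_dE_mV=0.0)
        ),
        "lower_potential": prepare_tcosa_model(
            model, thermo, cof3, PrepareOptions(third_cofactor_dE_mV=-155.0)
        ),
    }
    return t2, by_label


def test_identical_potential_third_pool_gives_zero_mdf_delta(three_pool_models):
    t2, by_label = three_pool_models
    df = compare_three_cofactor(t2, {"same_potential": by_label["same_potential"]}, GRID, "MDF")
    deltas = df.loc[df.model == "same_potential", "delta_vs_two_pool"]
    assert (deltas.abs() <= BAND).all()


def test_adding_a_cofactor_pool_never_hurts(three_pool_models):
    t2, by_label = three_pool_models
    df = compare_three_cofactor(t2, by_label, GRID, "MDF")
    assert (df["delta_vs_two_pool"] >= -BAND).all()
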