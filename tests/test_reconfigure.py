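"""Reconfiguration pipeline: splitting, dG0 rules, cofactor duplication."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcosa.model import (
    CofactorSpec,
    MetabolicModel,
    Metabolite,
    Reaction,
    Tag,
    ThermoAnnotation,
)
from tcosa.reconfigure import (
    assign_default_dG,
    duplicate_redox_reactions,
    impute_redox_dG_medians,
    prepare_tcosa_model,
    redox_potential_to_dG_shift,
    relax_to_feasibility,
    split_reversible,
    triplicate_redox_reactions,
    PrepareOptions,
)
from tcosa.milp import FluxConstraints, solve_mdf
from tcosa.toys import linear_chain


def model_with(reactions, mets=None, objective=None):
    met_ids = sorted({m for r in reactions for m in r.stoich})
    metabolites = {m: Metabolite(m) for m in (mets or met_ids)}
    return MetabolicModel(
        metabolites=metabolites,
        reactions={r.id: r for r in reactions},
        objective_reaction_id=objective or reactions[-1].id,
    )


# ------------------------------------------------------------- splitting
def test_split_reversible_creates_fwd_rev_pair_with_negated_dG():
    m = model_with(
        [Reaction("R", {"a": -1, "b": 1}, -5, 10), Reaction("EX_b", {"b": -1}, 0, 10)]
    )
    th = ThermoAnnotation(dG0={"R": 3.0}, dG0_source_tag={"R": Tag.COMPUTED})
    sm, sth = split_reversible(m, th)
    assert sm.reactions["R_FWD"].lb == 0 and sm.reactions["R_FWD"].ub == 10
    assert sm.reactions["R_REV"].lb == 0 and sm.reactions["R_REV"].ub == 5
    assert sm.reactions["R_REV"].stoich == {"a": 1, "b": -1}
    assert sth.dG0["R_FWD"] == 3.0 and sth.dG0["R_REV"] == -3.0


def test_split_keeps_sentinel_in_both_directions():
    m = model_with(
        [Reaction("R", {"a": -1, "b": 1}, -5, 10), Reaction("EX_b", {"b": -1}, 0, 10)]
    )
    th = ThermoAnnotation(dG0={"R": -100.0}, dG0_source_tag={"R": Tag.DEFAULT_SENTINEL})
    _, sth = split_reversible(m, th)
    assert sth.dG0["R_FWD"] == -100.0 and sth.dG0["R_REV"] == -100.0


def test_split_leaves_irreversible_reactions_untouched():
    m = model_with(
        [Reaction("R", {"a": -1, "b": 1}, 0, 10), Reaction("EX_b", {"b": -1}, 0, 10)]
    )
    sm, _ = split_reversible(m, ThermoAnnotation())
    assert set(sm.reactions) == {"R", "EX_b"}


@given(dG0=st.floats(-80, 80, allow_nan=False), lb=st.floats(-20, -0.1), ub=st.floats(0.1, 20))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_split_roundtrip_and_antisymmetry(dG0, lb, ub):
    """Merging FWD/REV recovers the original; computed dG0 is antisymmetric."""
    m = model_with(
        [Reaction("R", {"a": -1, "b": 2}, lb, ub), Reaction("EX_b", {"b": -1}, 0, 10)]
    )
    th = ThermoAnnotation(dG0={"R": dG0}, dG0_source_tag={"R": Tag.COMPUTED})
    sm, sth = split_reversible(m, th)
    fwd, rev = sm.reactions["R_FWD"], sm.reactions["R_REV"]
    assert fwd.stoich == {k: -v for k, v in rev.stoich.items()}
    assert (fwd.ub, -rev.ub) == (ub, lb)
    assert sth.dG0["R_FWD"] + sth.dG0["R_REV"] == 0.0


# ------------------------------------------------------------ dG defaults
def test_default_assignment_sentinel_exchange_and_computed():
    m = model_with(
        [
            Reaction("R_known", {"a": -1, "b": 1}, 0, 10),
            Reaction("R_unknown", {"b": -1, "c": 1}, 0, 10),
            Reaction("EX_c", {"c": -1}, 0, 10),
        ]
    )
    th = assign_default_dG(
        m, ThermoAnnotation(dG0={"R_known": 5.12}, dG0_source_tag={"R_known": Tag.COMPUTED})
    )
    assert th.dG0["R_known"] == 5.12 and th.dG0_source_tag["R_known"] == Tag.COMPUTED
    assert th.dG0["R_unknown"] == -100.0
    assert th.dG0_source_tag["R_unknown"] == Tag.DEFAULT_SENTINEL
    assert "EX_c" not in th.dG0 and th.dG0_source_tag["EX_c"] == Tag.UNCONSTRAINED


def test_pure_transporters_receive_sentinel_despite_computed_value():
    mets = {"a_c": Metabolite("a_c", "c"), "a_p": Metabolite("a_p", "p"), "b_c": Metabolite("b_c", "c")}
    m = MetabolicModel(
        metabolites=mets,
        reactions={
            "T": Reaction("T", {"a_p": -1, "a_c": 1}, 0, 10),
            "SINK": Reaction("SINK", {"a_c": -1, "b_c": 1}, 0, 10),
            "EX": Reaction("EX", {"b_c": -1}, 0, 10),
        },
        objective_reaction_id="EX",
    )
    th = assign_default_dG(m, ThermoAnnotation(dG0={"T": 1.0}, dG0_source_tag={}))
    assert th.dG0["T"] == -100.0
    assert th.dG0_source_tag["T"] == Tag.DEFAULT_SENTINEL


# ------------------------------------------------------- median imputation
def median_model():
    rxns = [
        Reaction(f"R{i}", {"a": -1, "nad_c": -1, "b": 1, "nadh_c": 1}, 0, 10)
        for i in range(4)
    ]
    rxns.append(Reaction("EX_b", {"b": -1}, 0, 10))
    return model_with(rxns)


def test_median_imputation_uses_median_of_computed_values():
    m = median_model()
    th = ThermoAnnotation(
        dG0={"R0": 2.0, "R1": 4.0, "R2": 9.0},
        dG0_source_tag={f"R{i}": Tag.COMPUTED for i in range(3)},
    )
    out = impute_redox_dG_medians(m, th, CofactorSpec())
    assert out.dG0["R3"] == 4.0
    assert out.dG0_source_tag["R3"] == Tag.MEDIAN_IMPUTED


def test_median_imputation_is_identity_when_all_annotated():
    m = median_model()
    th = ThermoAnnotation(
        dG0={f"R{i}": float(i) for i in range(4)},
        dG0_source_tag={f"R{i}": Tag.COMPUTED for i in range(4)},
    )
    out = impute_redox_dG_medians(m, th, CofactorSpec())
    assert out.dG0 == th.dG0


# -------------------------------------------------------------- duplication
def redox_split_model():
    rxns = [
        Reaction("CAT", {"a": -1, "nad_c": -1, "b": 1, "nadh_c": 1}, 0, 10),
        Reaction("REC", {"nadh_c": -1, "nad_c": 1}, 0, 10),
        Reaction("TH", {"nadh_c": -1, "nadp_c": -1, "nad_c": 1, "nadph_c": 1}, 0, 10),
        Reaction("EX_b", {"b": -1}, 0, 10),
    ]
    m = model_with(rxns, mets=["a", "b", "nad_c", "nadh_c", "nadp_c", "nadph_c"], objective="EX_b")
    th = ThermoAnnotation(
        dG0={"CAT": -10.0, "REC": -60.0, "TH": 0.0},
        dG0_source_tag={r: Tag.COMPUTED for r in ("CAT", "REC", "TH")},
    )
    return m, th


def test_duplication_creates_swapped_variant_with_identical_parameters():
    m, th = redox_split_model()
    t = duplicate_redox_reactions(m, th, CofactorSpec())
    orig = t.network.reactions["CAT_ORIGINAL_NAD_TCOSA"]
    var = t.network.reactions["CAT_VARIANT_NADP_TCOSA"]
    assert var.stoich == {"a": -1, "nadp_c": -1, "b": 1, "nadph_c": 1}
    assert (var.lb, var.ub) == (orig.lb, orig.ub)
    assert t.thermo.dG0[var.id] == t.thermo.dG0[orig.id]
    assert set(t.variant_groups["CAT"]) == {orig.id, var.id}


def test_dual_cofactor_reactions_are_never_duplicated():
    m, th = redox_split_model()
    t = duplicate_redox_reactions(m, th, CofactorSpec())
    assert "TH" in t.dual_cofactor_reaction_ids
    assert t.variant_groups["TH"] == ["TH"]


def test_reversible_redox_reaction_yields_four_variants():
    rxns = [
        Reaction("MDH", {"mal": -1, "nad_c": -1, "oaa": 1, "nadh_c": 1}, -10, 10),
        Reaction("EX", {"oaa": -1}, 0, 10),
    ]
    m = model_with(
        rxns,
        mets=["mal", "oaa", "nad_c", "nadh_c", "nadp_c", "nadph_c"],
        objective="EX",
    )
    th = ThermoAnnotation(dG0={"MDH": 10.0}, dG0_source_tag={"MDH": Tag.COMPUTED})
    sm, sth = split_reversible(m, th)
    t = duplicate_redox_reactions(sm, sth, CofactorSpec())
    members = set(t.variant_groups["MDH"])
    assert members == {
        "MDH_ORIGINAL_NAD_FWD_TCOSA",
        "MDH_VARIANT_NADP_FWD_TCOSA",
        "MDH_ORIGINAL_NAD_REV_TCOSA",
        "MDH_VARIANT_NADP_REV_TCOSA",
    }
    assert t.thermo.dG0["MDH_VARIANT_NADP_REV_TCOSA"] == -10.0


def test_variant_mass_difference_is_exactly_the_cofactor_substitution():
    m, th = redox_split_model()
    t = duplicate_redox_reactions(m, th, CofactorSpec())
    orig = t.network.reactions["CAT_ORIGINAL_NAD_TCOSA"].stoich
    var = t.network.reactions["CAT_VARIANT_NADP_TCOSA"].stoich
    diff = {k: var.get(k, 0) - orig.get(k, 0) for k in set(orig) | set(var)}
    diff = {k: v for k, v in diff.items() if v}
    assert diff == {"nad_c": 1, "nadh_c": -1, "nadp_c": -1, "nadph_c": 1}


# ------------------------------------------------------------- triplication
def three_pool_spec():
    return CofactorSpec(
        {
            "NAD": ("nad_c", "nadh_c"),
            "NADP": ("nadp_c", "nadph_c"),
            "NADZ": ("nadz_c", "nadzh_c"),
        }
    )


def test_triplication_at_zero_shift_copies_dG_unchanged():
    m, th = redox_split_model()
    t = triplicate_redox_reactions(m, th, three_pool_spec(), dE_shift_mV=0.0)
    assert len(t.variant_groups["CAT"]) == 3
    assert (
        t.thermo.dG0["CAT_VARIANT_NADZ_TCOSA"]
        == t.thermo.dG0["CAT_ORIGINAL_NAD_TCOSA"]
    )


def test_triplication_shifts_dG_by_potential_times_oxidized_coefficient():
    m, th = redox_split_model()
    t = triplicate_redox_reactions(m, th, three_pool_spec(), dE_shift_mV=-155.0)
    # CAT consumes 1 oxidized cofactor: lower potential -> reduction costs more
    assert t.thermo.dG0["CAT_VARIANT_NADZ_TCOSA"] == pytest.approx(-10.0 + 29.91035)
    # REC produces the oxidized cofactor: mirror image
    assert t.thermo.dG0["REC_VARIANT_NADZ_TCOSA"] == pytest.approx(-60.0 - 29.91035)


@pytest.mark.parametrize(
    "dE_mV, n, expected",
    [(-320.0, 2, 61.7504), (0.0, 2, 0.0), (155.0, 2, -29.91035)],
)
def test_redox_potential_to_gibbs_conversion(dE_mV, n, expected):
    assert redox_potential_to_dG_shift(dE_mV, n) == pytest.approx(expected, abs=1e-9)


# --------------------------------------------------------------- relaxation
def test_relaxation_returns_empty_set_on_feasible_model():
    model, thermo, cof = linear_chain(2)
    t = prepare_tcosa_model(model, thermo, cof)
    relaxed, t2 = relax_to_feasibility(t, 1.0, 0.1)
    assert relaxed == set()


def test_relaxation_identifies_the_insurmountable_reaction():
    model, thermo, cof = linear_chain(2, [0.0, 200.0])
    t = prepare_tcosa_model(model, thermo, cof)
    relaxed, t2 = relax_to_feasibility(t, 1.0, 0.1)
    assert relaxed == {"S2"}
    assert t2.thermo_active["S2"] is False
    sol = solve_mdf(t2, FluxConstraints(growth_min=1.0))
    assert sol.B >= 0.1


def test_relaxed_set_is_minimal_by_exhaustive_search():
    """Brute force: no strict subset of the returned relaxation suffices."""
    model, thermo, cof = linear_chain(3, [0.0, 200.0, 150.0])
    t = prepare_tcosa_model(model, thermo, cof)
    relaxed, _ = relax_to_feasibility(t, 1.0, 0.1)
    import itertools

    thermo_active = [rid for rid, a in t.thermo_active.items() if a]

    def feasible_with(dropped):
        t2 = t.copy()
        for rid in dropped:
            t2.thermo_active[rid] = False
        sol = solve_mdf(t2, FluxConstraints(growth_min=1.0))
        return sol.feasible and sol.B >= 0.1

    assert feasible_with(relaxed)
    # minimality: every smaller subset of thermo-active reactions fails
    for r in range(len(relaxed)):
        for combo in itertools.combinations(thermo_active, r):
            assert not feasible_with(set(combo))
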