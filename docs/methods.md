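# Methods

## The model

`tcosa` analyzes how the assignment of redox cofactor specificities —
which reactions use NAD(H) and which NADP(H) — shapes the thermodynamic
potential of a metabolic network. The central quantity is the network
max–min driving force (MDF): the largest bound *B* such that there exists
a steady-state flux distribution **r** and metabolite log-concentrations
**x** (within physiological bounds) for which every *active* reaction has
driving force

    f_i = −Δ_r G'°_i − RT · ν_iᵀ x  ≥  B,

where ν_i is reaction *i*'s column of the extended stoichiometric matrix
(internal and external species). A positive f_i means the reaction can
proceed forward; B > 0 means the whole flux distribution is
thermodynamically feasible, and a negative optimum measures the distance
from feasibility. The optimization is a MILP: binary indicators z_i are
forced to 1 by positive flux (r_i ≤ z_i β_i) and deactivate the
driving-force constraint through a big-M term (B ≤ f_i + M(1 − z_i)) when
a reaction is off.

**SubMDF** relaxes this: only a chosen reaction subset S (by default all
cofactor-variant reactions) must clear the maximized bound B_sub, while
every other active reaction only has to exceed a small feasibility floor
B_min (default 0.1 kJ/mol). This isolates redox-specific thermodynamic
effects from unrelated bottlenecks.

## Model reconfiguration

Starting from a plain stoichiometric model with a partial table of
standard reaction Gibbs energies:

1. **dG0 defaults.** Exchange and growth pseudo-reactions stay
   unconstrained. Pure transporters (reactant multiset equals product
   multiset up to the compartment suffix) and reactions without a value
   receive a −100 kJ/mol sentinel — low enough to impose only weak
   concentration constraints, but not nothing.
2. **Median imputation.** Redox reactions lacking a value get the median
   dG0 of all annotated reactions consuming the same cofactor species
   (computed on the pre-split reaction set to avoid double counting
   forward/backward copies).
3. **Irreversible splitting.** Every reversible reaction becomes a
   forward and a backward copy; dG0 is negated for the backward copy
   except for sentinel values, which keep −100 in both directions so
   neither direction is artificially favored.
4. **Cofactor expansion.** Every reaction using exactly one pool gains a
   copy with the other pool substituted (oxidized↔oxidized,
   reduced↔reduced) at identical coefficients, bounds and dG0 (the two
   couples have the same standard redox potential). Reactions touching
   both pools at once (transhydrogenase, NAD kinase, growth) are never
   duplicated. All copies derived from one original form a variant group;
   at most one group member may be active in any solution.
5. **Optional third pool.** A hypothetical couple at a shifted standard
   redox potential ΔE adds a third variant per group; its dG0 moves by
   −nFΔE (F = 96.485 kJ V⁻¹ mol⁻¹, n = 2) times the negated signed
   coefficient of the oxidized cofactor, so lowering the potential by
   155 mV makes each reduction of the new couple 29.91 kJ/mol more
   expensive (and each oxidation correspondingly easier).
6. **Feasibility repair.** If the demanded growth is thermodynamically
   infeasible, a MILP finds the minimum number of reactions whose
   driving-force constraints must be dropped to reach B ≥ B_min; those
   reactions are thereafter fully thermo-unconstrained (explicit
   `relaxed` tag — sentinel semantics are carried by tags, never by
   testing dG0 == −100).

## Scenarios and analyses

Four specificity regimes: **wild type** (swapped variants blocked),
**single pool** (all reactions on NAD(H); the growth reaction's NADP(H)
coefficients transferred one-to-one to NAD(H); remaining dual-cofactor
reactions blocked because they would couple the single pool to itself),
**flexible** (nothing blocked, the at-most-one constraint arbitrates), and
**random** (coin-flip assignments, with a free or a fixed —
wild-type-count-preserving — pool size; samples that are stoichiometrically
infeasible or give MDF < 0.1 kJ/mol are reported and disregarded, not
resampled).

Growth rates are swept on a descending grid: 99% of the FBA-maximal
growth rate, stepped down by 0.05 h⁻¹, with 0.05 h⁻¹ appended as the
smallest considered rate (values rounded to 3 decimals). The grid is
derived from the wild-type μ_max and shared across scenarios.

On top of the two solvers, the package provides: single-swap scans
(flip each duplicated reaction separately, record Δ(Sub)MDF, flag
stoichiometrically lethal swaps), minimal-swap MILPs (minimum number of
specificity flips for the wild type to reach the flexible optimum; one
binary per original reaction gates both direction copies of the
complementary variant), an activity census at a fixed optimum (maximize
each redox reaction's flux with the optimum re-imposed, so multiplicity
of optimal solutions is accounted for), a two- vs three-pool comparison,
and a variability analysis of
ρ = ln(([NADH]/[NAD⁺]) / ([NADPH]/[NADP⁺])) at the fixed optimum.

## Numerical choices

- Solver: HiGHS through `scipy.optimize.milp` / `linprog`; MIP relative
  gap 10⁻⁹.
- Big-M: per-model bound max_i(−dG0_i + RT Σ_m |ν_mi| max(|ln c_min|,
  |ln c_max|)) + 1, provably above any attainable driving force; audited
  after every solve. A fixed value can be configured. B's lower bound
  uses the analogous |dG0| magnitude bound so negative optima are never
  truncated.
- Concentrations default to 10⁻⁶–0.02 M at 298.15 K; protons/water-like
  species can be pinned to 1 M (they contribute 0 to driving forces and
  stay in the stoichiometry).
- "Active" means flux > 10⁻⁶ (a solver may set z = 1 at zero flux).
- Optima re-imposed in follow-up problems (swap minimization, census,
  ratio ranges) use a one-sided bound at optimum − 10⁻³ kJ/mol rather
  than an equality, avoiding MILP equality brittleness. All scenario
  comparisons use the same 10⁻³ kJ/mol band.
- Infinite flux bounds are capped at 1000 mmol gDW⁻¹ h⁻¹ (the activity
  coupling r ≤ z·β needs finite β).
- Stoichiometric infeasibility (no admissible flux distribution) is
  reported as a distinct status; thermodynamic strain appears as a
  finite, possibly negative, B instead.

## Synthetic networks and what they show

The toy generator produces fully specified small networks:

- **Linear chains** with per-step dG0; with all dG0 = 0 the MDF has the
  closed form RT·ln(c_max/c_min)/n (24.55 kJ/mol for one step, 12.27 for
  two, at the default range), used as exact anchors.
- **The redox fixture**: an NAD⁺-reducing catabolic branch (CAT, dG0 0)
  whose NADH is reoxidized by a respiration-like sink (−60 kJ/mol), an
  oxidative NADPH-producing branch (PPP, −30 kJ/mol) with an overflow
  valve, an NADPH-consuming anabolic step (ANA, dG0 0) and a biomass sink
  with a 0.2 NADPH demand. Parameters were chosen once so that the
  network is *wild-type adapted*, as the organism-scale analyses assume:
  the wild-type assignment attains the flexible optimum, collapsing both
  pools onto NAD(H) costs driving force, and a high MDF forces the NAD
  pool oxidized and the NADP pool reduced (ratio quotient < 1).
- **Seeded random toys** (2–3 step chains, random dG0 in [−12, 6] kJ/mol,
  optional redox coupling, bypass and reversibility) small enough for the
  enumeration oracle, which solves the same problem by exhausting all
  admissible active sets with two LPs each.

These networks exercise every code path (both pools, duplication,
splitting, dual-cofactor handling, infeasible swaps) but are far from
genome-scale data in important ways: they have no compartments or
membrane-potential-corrected dG0 values, no uncertainty in the Gibbs
energies, and single-digit reaction counts, so passing tests demonstrate
correctness of the optimization machinery and the reconfiguration
bookkeeping — not biological conclusions. Genome-scale runs require an
SBML model and a dG0 table as external inputs (`tcosa prepare --model
iML1515.xml --dG dg.tsv ...`); with those, the pipeline reproduces the
published model statistics and FBA growth rates.

## Problem sizes

The default verification suite uses ≥ 20 random toys (≤ 14 reactions
after expansion) for oracle agreement, 100 random specificity samples on
the fixture, and 2–3 growth-rate set points per scenario comparison —
sizes chosen so the whole analysis reruns in seconds while every
qualitative comparison (scenario ordering, swap counts, ratio trend,
three-pool deltas) remains strict.

## Known limitations

- The enumeration oracle is exponential and guarded at 14 reactions.
- Relaxation minimality is unique only up to ties; the MILP returns one
  optimal set (alternate optima could be enumerated via integer cuts).
- dG0 values are taken as given; no component-contribution estimation,
  multi-compartment pH corrections, or consistent resampling of Gibbs
  energies is performed.
- Enzyme kinetics/costs are outside the scope: a high MDF indicates
  thermodynamic headroom, not realized fluxes.
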