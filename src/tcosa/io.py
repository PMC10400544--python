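"""File I/O: toy-JSON model dialect, SBML, dG0 tables and result files.

The toy-JSON dialect (schema ``tcosa-toy/1``) is the canonical format for
small self-contained instances: it bundles stoichiometry, flux bounds,
thermodynamic annotation and the cofactor pool definition in one file.
Genome-scale models are read from SBML (level 3 + FBC) through COBRApy.
A reconfigured model is stored as ``tcosa-model/1`` JSON including variant
groups and provenance so downstream commands need not re-derive them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .model import (
    CofactorSpec,
    ConfigurationError,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionProvenance,
    TcosaModel,
    ThermoAnnotation,
)

__all__ = [
    "load_model",
    "load_toy_json",
    "save_toy_json",
    "read_sbml",
    "write_sbml",
    "read_dG_table",
    "write_dG_table",
    "save_tcosa_json",
    "load_tcosa_json",
    "solution_to_frame",
    "write_solution_json",
    "write_results_csv",
    "read_results_csv",
    "run_metadata",
]

logger = logging.getLogger("tcosa")

TOY_SCHEMA = "tcosa-toy/1"
MODEL_SCHEMA = "tcosa-model/1"
RESULTS_SCHEMA = "tcosa-results/1"


def load_model(path: str | Path, dialect: str | None = None):
    """Load a model file, auto-detecting SBML (.xml/.sbml) vs toy-JSON.

    Returns ``(MetabolicModel, ThermoAnnotation | None, CofactorSpec | None)``;
    SBML carries no thermodynamic annotation, so those slots are None and
    a dG0 table must be supplied separately.
    """
    path = Path(path)
    if dialect is None:
        dialect = "SBML" if path.suffix.lower() in (".xml", ".sbml") else "toy-JSON"
    if dialect == "SBML":
        return read_sbml(path), None, None
    if dialect == "toy-JSON":
        return load_toy_json(path)
    raise ConfigurationError(f"unknown model dialect {dialect!r}")


# ---------------------------------------------------------------- toy JSON
def load_toy_json(path: str | Path):
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != TOY_SCHEMA:
        raise ConfigurationError(
            f"{path}: expected schema {TOY_SCHEMA!r}, found {doc.get('schema')!r}"
        )
    return _parse_toy_doc(doc, str(path))


def _parse_toy_doc(doc: dict, where: str = "<doc>"):
    mets: dict[str, Metabolite] = {}
    thermo = ThermoAnnotation(temperature=doc.get("temperature", 298.15))
    for m in doc["metabolites"]:
        mets[m["id"]] = Metabolite(
            m["id"], m.get("compartment", "c"), m.get("external", False)
        )
        if "c_min" in m:
            thermo.c_min[m["id"]] = m["c_min"]
        if "c_max" in m:
            thermo.c_max[m["id"]] = m["c_max"]
        if m.get("fixed_unit"):
            thermo.fixed_unit_species.add(m["id"])
    rxns: dict[str, Reaction] = {}
    for r in doc["reactions"]:
        rxns[r["id"]] = Reaction(r["id"], dict(r["stoich"]), r.get("lb", 0.0), r.get("ub", 1000.0))
        if "dG0" in r and r["dG0"] is not None:
            thermo.dG0[r["id"]] = r["dG0"]
            thermo.dG0_source_tag[r["id"]] = r.get("dG0_tag", "computed")
    if "objective" not in doc:
        raise ConfigurationError(f"{where}: missing objective reaction")
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_reaction_id=doc["objective"],
        exchange_reaction_ids=set(doc.get("exchanges", [])),
    )
    model.validate()
    cof = None
    if "cofactors" in doc:
        cof = CofactorSpec({k: tuple(v) for k, v in doc["cofactors"].items()})
        cof.validate()
    return model, thermo, cof


def save_toy_json(
    path: str | Path,
    model: MetabolicModel,
    thermo: ThermoAnnotation | None = None,
    cofactors: CofactorSpec | None = None,
) -> None:
    with open(path, "w") as fh:
        json.dump(_toy_doc(model, thermo, cofactors), fh, indent=1)


def _toy_doc(
    model: MetabolicModel,
    thermo: ThermoAnnotation | None = None,
    cofactors: CofactorSpec | None = None,
) -> dict:
    thermo = thermo or ThermoAnnotation()
    doc = {
        "schema": TOY_SCHEMA,
        "temperature": thermo.temperature,
        "metabolites": [
            {
                "id": m.id,
                "compartment": m.compartment,
                "external": m.external,
                **(
                    {"c_min": thermo.c_min[m.id]} if m.id in thermo.c_min else {}
                ),
                **(
                    {"c_max": thermo.c_max[m.id]} if m.id in thermo.c_max else {}
                ),
                **({"fixed_unit": True} if m.id in thermo.fixed_unit_species else {}),
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": r.stoich,
                "lb": r.lb,
                "ub": r.ub,
                **({"dG0": thermo.dG0[r.id]} if r.id in thermo.dG0 else {}),
                **(
                    {"dG0_tag": thermo.dG0_source_tag[r.id]}
                    if r.id in thermo.dG0_source_tag
                    else {}
                ),
            }
            for r in model.reactions.values()
        ],
        "objective": model.objective_reaction_id,
        "exchanges": sorted(model.exchange_reaction_ids),
    }
    if cofactors is not None:
        doc["cofactors"] = {k: list(v) for k, v in cofactors.pools.items()}
    return doc


# -------------------------------------------------------------------- SBML
def read_sbml(path: str | Path) -> MetabolicModel:
    """Read an SBML (FBC) model through COBRApy."""
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises various parser errors
        raise ConfigurationError(f"SBML parse failure for {path}: {exc}") from exc
    return from_cobra(cm)


def from_cobra(cm) -> MetabolicModel:
    mets = {
        m.id: Metabolite(m.id, m.compartment or "c", external=False)
        for m in cm.metabolites
    }
    rxns = {
        r.id: Reaction(
            r.id,
            {m.id: float(c) for m, c in r.metabolites.items()},
            float(r.lower_bound),
            float(r.upper_bound),
        )
        for r in cm.reactions
    }
    objective = None
    for r in cm.reactions:
        if r.objective_coefficient:
            objective = r.id
            break
    if objective is None:
        raise ConfigurationError("SBML model has no objective reaction")
    exchanges = {r.id for r in cm.exchanges}
    model = MetabolicModel(mets, rxns, objective, exchanges)
    model.validate()
    return model


def to_cobra(model: MetabolicModel, model_id: str = "tcosa_model"):
    import cobra

    cm = cobra.Model(model_id)
    cmets = {}
    for m in model.metabolites.values():
        cmets[m.id] = cobra.Metabolite(m.id, compartment=m.compartment or "c")
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id, lower_bound=r.lb, upper_bound=r.ub)
        crxns.append(cr)
    cm.add_reactions(crxns)
    for r in model.reactions.values():
        cm.reactions.get_by_id(r.id).add_metabolites(
            {cmets[m]: c for m, c in r.stoich.items()}
        )
    cm.objective = model.objective_reaction_id
    return cm


def write_sbml(path: str | Path, model: MetabolicModel) -> None:
    import cobra.io

    cobra.io.write_sbml_model(to_cobra(model), str(path))


# --------------------------------------------------------------- dG tables
def read_dG_table(path: str | Path) -> tuple[dict[str, float], dict[str, str]]:
    """TSV with columns reaction_id, dG0_kJ_mol, source_tag (optional)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "reaction_id" not in df or "dG0_kJ_mol" not in df:
        raise ConfigurationError(f"{path}: need columns reaction_id, dG0_kJ_mol")
    dG0 = dict(zip(df["reaction_id"], df["dG0_kJ_mol"].astype(float)))
    tags = (
        dict(zip(df["reaction_id"], df["source_tag"]))
        if "source_tag" in df
        else {rid: "computed" for rid in dG0}
    )
    return dG0, tags


def write_dG_table(path: str | Path, thermo: ThermoAnnotation) -> None:
    rows = [
        {
            "reaction_id": rid,
            "dG0_kJ_mol": thermo.dG0.get(rid),
            "source_tag": thermo.dG0_source_tag.get(rid, ""),
        }
        for rid in sorted(set(thermo.dG0) | set(thermo.dG0_source_tag))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------- reconfigured model
def save_tcosa_json(path: str | Path, tcosa: TcosaModel) -> None:
    doc = {
        "schema": MODEL_SCHEMA,
        "network": _toy_doc(tcosa.network, tcosa.thermo, tcosa.cofactors),
        "variant_groups": tcosa.variant_groups,
        "provenance": {
            rid: {
                "original_id": p.original_id,
                "direction": p.direction,
                "pool": p.pool,
                "is_variant": p.is_variant,
            }
            for rid, p in tcosa.provenance.items()
        },
        "thermo_active": tcosa.thermo_active,
        "dual_cofactor_reaction_ids": sorted(tcosa.dual_cofactor_reaction_ids),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_tcosa_json(path: str | Path) -> TcosaModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != MODEL_SCHEMA:
        raise ConfigurationError(
            f"{path}: expected schema {MODEL_SCHEMA!r}, found {doc.get('schema')!r}"
        )
    model, thermo, cof = _parse_toy_doc(doc["network"], str(path))
    tcosa = TcosaModel(
        network=model,
        thermo=thermo,
        cofactors=cof or CofactorSpec(),
        variant_groups={k: list(v) for k, v in doc["variant_groups"].items()},
        provenance={
            rid: ReactionProvenance(
                p["original_id"], p["direction"], p["pool"], p["is_variant"]
            )
            for rid, p in doc["provenance"].items()
        },
        thermo_active=dict(doc["thermo_active"]),
        dual_cofactor_reaction_ids=set(doc["dual_cofactor_reaction_ids"]),
    )
    tcosa.validate()
    return tcosa


# ----------------------------------------------------------------- results
def solution_to_frame(sol) -> pd.DataFrame:
    """Flat per-reaction table of a solved instance."""
    rows = []
    for rid, flux in sol.fluxes.items():
        rows.append(
            {
                "reaction_id": rid,
                "flux": flux,
                "z": sol.z.get(rid),
                "driving_force_kJ_mol": sol.driving_forces.get(rid),
                "active": rid in sol.active_reactions,
            }
        )
    return pd.DataFrame(rows)


def write_solution_json(path: str | Path, sol) -> None:
    doc = {
        "schema": RESULTS_SCHEMA,
        "B": sol.B,
        "B_sub": sol.B_sub,
        "status": sol.status,
        "fluxes": sol.fluxes,
        "log_concentrations": sol.log_concentrations,
        "driving_forces": sol.driving_forces,
        "active_set": sorted(sol.active_reactions),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def write_results_csv(path: str | Path, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {RESULTS_SCHEMA}\n")
        df.to_csv(fh, index=False)


def read_results_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_metadata(config=None, seed: int | None = None) -> dict:
    """Reproducibility stamp: solver, versions, seed, config hash."""
    import scipy

    cfg_repr = repr(config) if config is not None else ""
    meta = {
        "solver": "highs (scipy.optimize.milp)",
        "scipy_version": scipy.__version__,
        "seed": seed,
        "config_hash": hashlib.sha256(cfg_repr.encode()).hexdigest()[:12],
    }
    logger.info("run metadata: %s", meta)
    return meta
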