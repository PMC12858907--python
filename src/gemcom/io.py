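"""Readers and writers: toy JSON dialect, SBML L3-FBC, media TSV.

The toy JSON dialect is a deliberately small interchange format for
generated models::

    {"strain_id": ...,
     "metabolites": [{"id", "compartment", "formula"?, "name"?, "charge"?}],
     "reactions":   [{"id", "stoich": {met: coef}, "lb", "ub",
                      "exchange"?, "biomass"?}]}

SBML reading/writing goes through COBRApy (the community-standard SBML
FBC implementation); models are converted to and from the package's own
containers at the boundary.  Biomass detection order on load: explicit
flag > objective annotation > reaction id containing "biomass"
(case-insensitive); any ambiguity is an error, never a silent pick.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from .core import FormatError, Medium, Metabolite, ModelError, Reaction, StrainModel

__all__ = [
    "load_strain_model",
    "read_medium_tsv",
    "write_medium_tsv",
    "write_sbml",
    "write_solution_json",
    "write_toy_json",
]


def load_strain_model(path, dialect: str = "toy_json") -> StrainModel:
    """Load one strain model from ``toy_json`` or ``sbml_fbc``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"model file not found: {path}")
    if dialect == "toy_json":
        return _load_toy_json(path)
    if dialect == "sbml_fbc":
        return _load_sbml(path)
    raise FormatError(f"unknown model dialect {dialect!r}")


# ---------------------------------------------------------------------------
# toy_json
# ---------------------------------------------------------------------------

def _load_toy_json(path: Path) -> StrainModel:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    for key in ("strain_id", "metabolites", "reactions"):
        if key not in payload:
            raise FormatError(f"{path}: missing top-level key {key!r}")
    metabolites = []
    for entry in payload["metabolites"]:
        if "id" not in entry or "compartment" not in entry:
            raise FormatError(f"{path}: metabolite entry missing id/compartment: {entry}")
        metabolites.append(
            Metabolite(
                id=entry["id"],
                compartment=entry["compartment"],
                name=entry.get("name", ""),
                formula=entry.get("formula"),
                charge=entry.get("charge"),
            )
        )
    reactions = []
    for entry in payload["reactions"]:
        if "id" not in entry or "stoich" not in entry:
            raise FormatError(f"{path}: reaction entry missing id/stoich: {entry}")
        reactions.append(
            Reaction(
                id=entry["id"],
                stoichiometry={m: float(v) for m, v in entry["stoich"].items()},
                lower_bound=float(entry.get("lb", -1000.0)),
                upper_bound=float(entry.get("ub", 1000.0)),
                is_exchange=bool(entry.get("exchange", False)),
                is_biomass=bool(entry.get("biomass", False)),
            )
        )
    if not any(r.is_biomass for r in reactions):
        reactions = _flag_biomass_by_name(reactions, str(path))
    return StrainModel(payload["strain_id"], metabolites, reactions)


def _flag_biomass_by_name(reactions: List[Reaction], origin: str) -> List[Reaction]:
    hits = [r for r in reactions if "biomass" in r.id.lower()]
    if len(hits) != 1:
        raise ModelError(
            f"{origin}: cannot identify a unique biomass reaction "
            f"({len(hits)} candidates by name)"
        )
    hits[0].is_biomass = True
    return reactions


def write_toy_json(model: StrainModel, path) -> None:
    payload = {
        "strain_id": model.strain_id,
        "metabolites": [
            {
                "id": m.id,
                "compartment": m.compartment,
                **({"name": m.name} if m.name else {}),
                **({"formula": m.formula} if m.formula else {}),
                **({"charge": m.charge} if m.charge is not None else {}),
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": dict(r.stoichiometry),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "exchange": r.is_exchange,
                "biomass": r.is_biomass,
            }
            for r in model.reactions.values()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# SBML via COBRApy
# ---------------------------------------------------------------------------

def _load_sbml(path: Path) -> StrainModel:
    import cobra.io

    try:
        cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # libsbml raises a zoo of types
        raise FormatError(f"{path}: SBML parse failure ({exc})") from exc
    return from_cobra(cmodel, strain_id=cmodel.id or path.stem)


def from_cobra(cmodel, strain_id: Optional[str] = None) -> StrainModel:
    """Convert a COBRApy model; compartments are mapped onto 'e'/'c' by
    membership in the model's boundary metabolites."""
    extracellular = {m.id for r in cmodel.exchanges for m in r.metabolites}
    metabolites = [
        Metabolite(
            id=m.id,
            compartment="e" if m.id in extracellular else "c",
            name=m.name or "",
            formula=m.formula or None,
            charge=m.charge,
        )
        for m in cmodel.metabolites
    ]
    objective_ids = {
        r.id for r in cmodel.reactions if abs(r.objective_coefficient) > 0
    }
    if len(objective_ids) > 1:
        raise ModelError(
            f"{cmodel.id}: ambiguous biomass ({len(objective_ids)} objective reactions)"
        )
    exchange_ids = {r.id for r in cmodel.exchanges}
    reactions = []
    for r in cmodel.reactions:
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                is_exchange=r.id in exchange_ids,
                is_biomass=r.id in objective_ids,
            )
        )
    if not objective_ids:
        reactions = _flag_biomass_by_name(reactions, cmodel.id or "sbml model")
    return StrainModel(strain_id or cmodel.id, metabolites, reactions)


def to_cobra(model: StrainModel):
    """Convert to a COBRApy model (for SBML export or cross-checks)."""
    import cobra

    cmodel = cobra.Model(model.strain_id)
    cmets = {}
    for m in model.metabolites.values():
        cm = cobra.Metabolite(
            m.id, name=m.name or m.id, compartment=m.compartment,
            formula=m.formula, charge=m.charge,
        )
        cmets[m.id] = cm
    cmodel.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        crxns.append(cr)
    cmodel.add_reactions(crxns)
    for r in model.reactions.values():
        cmodel.reactions.get_by_id(r.id).add_metabolites(
            {cmets[m]: coef for m, coef in r.stoichiometry.items()}
        )
    cmodel.objective = model.biomass_reaction.id
    return cmodel


def write_sbml(model: StrainModel, path) -> None:
    import cobra.io

    cobra.io.write_sbml_model(to_cobra(model), str(path))


# ---------------------------------------------------------------------------
# Media and solutions
# ---------------------------------------------------------------------------

def read_medium_tsv(path, name: Optional[str] = None) -> Medium:
    """TSV with columns metabolite_id, amount_mmol_per_gDW; '#' comments."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"metabolite_id", "amount_mmol_per_gDW"}
    if not required <= set(frame.columns):
        raise FormatError(
            f"medium TSV {path} must have columns {sorted(required)}"
        )
    amounts = {
        str(row["metabolite_id"]): float(row["amount_mmol_per_gDW"])
        for _, row in frame.iterrows()
    }
    return Medium(name=name or Path(path).stem, amounts=amounts)


def write_medium_tsv(medium: Medium, path) -> None:
    pd.DataFrame(
        sorted(medium.amounts.items()),
        columns=["metabolite_id", "amount_mmol_per_gDW"],
    ).to_csv(path, sep="\t", index=False)


def write_solution_json(solution, path) -> None:
    """Community solution dump (scenario, objective, biomass, pool flows)."""
    Path(path).write_text(json.dumps(solution.to_dict(), indent=1, sort_keys=True) + "\n")
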