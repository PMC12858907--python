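"""Core containers for strain-level metabolic models.

A strain model is the classical constraint-based representation: a set of
metabolites partitioned into compartments (at minimum cytosol ``c`` and
extracellular ``e``), a set of reactions with flux bounds, a sparse
stoichiometric matrix ``S``, one designated biomass pseudo-reaction whose
flux is the growth readout, and boundary (exchange) reactions that move a
single extracellular metabolite in or out of the system.

Sign convention for exchange fluxes: positive = secretion into the
environment, negative = uptake.  A medium entry of ``a`` mmol/gDW for
metabolite ``m`` therefore bounds the exchange flux of ``m`` below by
``-a`` (never looser than the model's own uptake capacity).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
from scipy import sparse

__all__ = [
    "ATOMIC_WEIGHTS",
    "FluxSolution",
    "Medium",
    "Metabolite",
    "ModelError",
    "FormatError",
    "QCFinding",
    "QCReport",
    "Reaction",
    "SolverStatus",
    "StrainModel",
    "parse_formula",
    "is_inorganic",
    "molecular_weight",
]

# IUPAC 2021 standard atomic weights, 5 significant figures.
ATOMIC_WEIGHTS: Dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Na": 22.990, "K": 39.098, "Cl": 35.45, "Mg": 24.305,
    "Ca": 40.078, "Fe": 55.845, "Zn": 65.38, "Br": 79.904, "Mn": 54.938,
    "Cu": 63.546, "Co": 58.933, "Mo": 95.95, "Se": 78.971, "I": 126.90,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_FORMULA_FULL = re.compile(r"^(?:[A-Z][a-z]?\d*)+$")


class ModelError(ValueError):
    """A model violates a structural invariant."""


class FormatError(ValueError):
    """A file could not be parsed under the requested dialect."""


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a flat Hill-style elemental formula (e.g. ``C6H12O6``).

    Returns element -> count.  Raises :class:`FormatError` on anything that
    is not a plain element/count sequence (no parentheses, no charges).
    """
    if not formula or not _FORMULA_FULL.match(formula):
        raise FormatError(f"cannot parse elemental formula {formula!r}")
    counts: Dict[str, int] = {}
    for element, digits in _FORMULA_TOKEN.findall(formula):
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    return counts


def is_inorganic(formula: Optional[str]) -> bool:
    """True when the formula parses and contains neither carbon nor nitrogen.

    Metabolites without a formula are conservatively treated as organic.
    """
    if formula is None:
        return False
    try:
        counts = parse_formula(formula)
    except FormatError:
        return False
    return counts.get("C", 0) == 0 and counts.get("N", 0) == 0


def molecular_weight(formula: str) -> float:
    """Molar mass in g/mol from a flat elemental formula."""
    counts = parse_formula(formula)
    unknown = sorted(set(counts) - set(ATOMIC_WEIGHTS))
    if unknown:
        raise FormatError(f"no atomic weight for element(s) {unknown} in {formula!r}")
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in counts.items())


class SolverStatus(str, enum.Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    name: str = ""
    formula: Optional[str] = None
    charge: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("metabolite id must be non-empty")


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    is_exchange: bool = False
    is_biomass: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )


class StrainModel:
    """One species' stoichiometric network with bounds and flags.

    Invariants enforced at construction:

    * metabolite/reaction ids unique, stoichiometry references declared
      metabolites only;
    * exactly one biomass reaction;
    * the exchange set is exactly the reactions touching a single
      metabolite that lives in compartment ``e``.
    """

    def __init__(
        self,
        strain_id: str,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
    ) -> None:
        if not strain_id:
            raise ModelError("strain_id must be non-empty")
        self.strain_id = strain_id
        self.metabolites: Dict[str, Metabolite] = {}
        for met in metabolites:
            if met.id in self.metabolites:
                raise ModelError(f"duplicate metabolite id {met.id!r}")
            self.metabolites[met.id] = met
        self.reactions: Dict[str, Reaction] = {}
        for rxn in reactions:
            if rxn.id in self.reactions:
                raise ModelError(f"duplicate reaction id {rxn.id!r}")
            self.reactions[rxn.id] = rxn
        self._validate()

    # -- structural checks -------------------------------------------------
    def _validate(self) -> None:
        biomass = [r for r in self.reactions.values() if r.is_biomass]
        if len(biomass) != 1:
            raise ModelError(
                f"strain {self.strain_id!r}: expected exactly one biomass "
                f"reaction, found {len(biomass)}"
            )
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise FormatError(
                        f"reaction {rxn.id!r} cites undeclared metabolite {met_id!r}"
                    )
            structural_exchange = self._is_structural_exchange(rxn)
            if rxn.is_exchange != structural_exchange:
                raise ModelError(
                    f"reaction {rxn.id!r}: is_exchange={rxn.is_exchange} but the "
                    f"structure says {structural_exchange} (an exchange touches "
                    "exactly one metabolite, in compartment 'e')"
                )

    def _is_structural_exchange(self, rxn: Reaction) -> bool:
        if len(rxn.stoichiometry) != 1:
            return False
        (met_id,) = rxn.stoichiometry
        return self.metabolites[met_id].compartment == "e"

    # -- views -------------------------------------------------------------
    @property
    def biomass_reaction(self) -> Reaction:
        return next(r for r in self.reactions.values() if r.is_biomass)

    @property
    def exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def exchange_metabolite(self, rxn_id: str) -> str:
        rxn = self.reactions[rxn_id]
        if not rxn.is_exchange:
            raise ModelError(f"reaction {rxn_id!r} is not an exchange")
        (met_id,) = rxn.stoichiometry
        return met_id

    @property
    def transport_reactions(self) -> List[Reaction]:
        """Reactions spanning the 'e' and 'c' compartments."""
        out = []
        for rxn in self.reactions.values():
            comps = {self.metabolites[m].compartment for m in rxn.stoichiometry}
            if "e" in comps and "c" in comps:
                out.append(rxn)
        return out

    def stoichiometric_matrix(self):
        """Sparse S (metabolites x reactions) plus the row/column id orders."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        mat = sparse.lil_matrix((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for met_id, coef in self.reactions[rid].stoichiometry.items():
                mat[met_index[met_id], j] = coef
        return mat.tocsr(), met_ids, rxn_ids

    def copy(self) -> "StrainModel":
        return StrainModel(
            self.strain_id,
            list(self.metabolites.values()),
            [
                Reaction(
                    r.id, dict(r.stoichiometry), r.lower_bound, r.upper_bound,
                    r.is_exchange, r.is_biomass,
                )
                for r in self.reactions.values()
            ],
        )

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"StrainModel({self.strain_id!r}, {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions)"
        )


def _medium_keys(met_id: str) -> tuple:
    """Acceptable medium keys for an extracellular metabolite: the id as
    declared and, when present, the id without its '_e' compartment tag,
    so media can name bare compounds ('glc' matches 'glc_e')."""
    if met_id.endswith("_e"):
        return (met_id, met_id[:-2])
    return (met_id,)


@dataclass
class Medium:
    """Available extracellular amounts in mmol/gDW.

    Metabolites absent from :attr:`amounts` fall back on the inorganic
    rule: compounds whose formula contains neither C nor N receive
    :attr:`default_inorganic_amount` (1000 mmol/gDW by default); every
    other absent metabolite — including those without a formula — receives
    0, so unknown compounds are never silently fed.
    """

    name: str
    amounts: Dict[str, float] = field(default_factory=dict)
    default_inorganic_amount: float = 1000.0

    def __post_init__(self) -> None:
        for met_id, amount in self.amounts.items():
            if amount < 0:
                raise ModelError(
                    f"medium {self.name!r}: negative amount for {met_id!r}"
                )

    def amount_for(self, metabolite: Metabolite) -> float:
        for key in _medium_keys(metabolite.id):
            if key in self.amounts:
                return self.amounts[key]
        if is_inorganic(metabolite.formula):
            return self.default_inorganic_amount
        return 0.0


@dataclass
class FluxSolution:
    fluxes: Dict[str, float]
    objective_value: float
    status: SolverStatus

    @property
    def ok(self) -> bool:
        return self.status is SolverStatus.OPTIMAL


@dataclass
class QCFinding:
    check: str
    target: str
    status: str  # PASS | FAIL | SKIP
    detail: str = ""


class QCReport(list):
    """List of QC findings with TSV export (check, target, status, detail)."""

    @property
    def failures(self) -> List[QCFinding]:
        return [f for f in self if f.status == "FAIL"]

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            [
                {"check": f.check, "target": f.target, "status": f.status,
                 "detail": f.detail}
                for f in self
            ],
            columns=["check", "target", "status", "detail"],
        ).to_csv(path, sep="\t", index=False)


def namespaced(strain_id: str, item_id: str) -> str:
    """Community-wide id for a strain-local reaction or metabolite."""
    return f"{strain_id}:{item_id}"


def build_medium_from_mapping(name: str, amounts: Mapping[str, float]) -> Medium:
    return Medium(name=name, amounts=dict(amounts))


def as_float_array(values: Iterable[float]) -> np.ndarray:
    return np.asarray(list(values), dtype=float)
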