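"""Single-strain flux balance analysis and model quality control.

FBA maximizes the biomass flux subject to steady state ``S v = 0`` and
flux bounds; the medium enters through exchange lower bounds (uptake is
negative flux, so an available amount ``a`` bounds the exchange below by
``-a``, never looser than the model's own uptake capacity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .core import (
    FluxSolution,
    Medium,
    ModelError,
    QCFinding,
    QCReport,
    SolverStatus,
    StrainModel,
    parse_formula,
)

logger = logging.getLogger(__name__)

#: bound used when an exchange is "fully open" during QC
OPEN_BOUND = 1000.0
#: fluxes below this magnitude are treated as zero everywhere
FLUX_EPSILON = 1e-6
#: residual tolerance for steady-state verification of returned solutions
BALANCE_TOL = 1e-6


@dataclass
class LinearProblem:
    """max c.x  s.t.  A_eq x = b_eq,  A_ub x <= b_ub,  lb <= x <= ub."""

    c: np.ndarray
    A_eq: np.ndarray
    b_eq: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    variables: List[str]
    A_ub: Optional[np.ndarray] = None
    b_ub: Optional[np.ndarray] = None


def solve_linear_problem(problem: LinearProblem):
    """Solve with HiGHS; returns (status, x, objective)."""
    res = linprog(
        -problem.c,
        A_eq=problem.A_eq if problem.A_eq.size else None,
        b_eq=problem.b_eq if problem.A_eq.size else None,
        A_ub=problem.A_ub,
        b_ub=problem.b_ub,
        bounds=list(zip(problem.lb, problem.ub)),
        method="highs",
    )
    if res.status == 0:
        return SolverStatus.OPTIMAL, res.x, float(problem.c @ res.x)
    if res.status == 2:
        return SolverStatus.INFEASIBLE, None, float("nan")
    if res.status == 3:
        return SolverStatus.UNBOUNDED, None, float("inf")
    raise RuntimeError(f"LP solver failed: {res.message}")  # pragma: no cover


def effective_exchange_bounds(
    model: StrainModel, medium: Medium
) -> Dict[str, tuple]:
    """Exchange bounds after applying the medium.

    Lower bound = max(intrinsic LB, -available amount): the tighter of the
    strain's uptake capacity and what the environment offers.  Secretion
    upper bounds are left as declared.  Medium entries that match no
    exchange metabolite are ignored with a warning.
    """
    from .core import _medium_keys

    exchange_mets = {model.exchange_metabolite(r.id): r for r in model.exchange_reactions}
    acceptable = {key for met in exchange_mets for key in _medium_keys(met)}
    unmatched = sorted(set(medium.amounts) - acceptable)
    if unmatched:
        logger.warning(
            "medium %r: %d entr%s match no exchange metabolite of strain %r: %s",
            medium.name, len(unmatched), "y" if len(unmatched) == 1 else "ies",
            model.strain_id, ", ".join(unmatched),
        )
    bounds = {}
    for met_id, rxn in exchange_mets.items():
        amount = medium.amount_for(model.metabolites[met_id])
        bounds[rxn.id] = (max(rxn.lower_bound, -amount), rxn.upper_bound)
    return bounds


def build_fba_problem(
    model: StrainModel,
    medium: Optional[Medium],
    objective_reaction: Optional[str] = None,
    exchange_bounds: Optional[Dict[str, tuple]] = None,
) -> LinearProblem:
    """Assemble the FBA linear program (shared by solver and oracle tests)."""
    S, _met_ids, rxn_ids = model.stoichiometric_matrix()
    if objective_reaction is None:
        objective_reaction = model.biomass_reaction.id
    if objective_reaction not in model.reactions:
        raise ModelError(f"unknown objective reaction {objective_reaction!r}")
    if exchange_bounds is None:
        exchange_bounds = (
            effective_exchange_bounds(model, medium) if medium is not None else {}
        )
    lb, ub = [], []
    for rid in rxn_ids:
        rxn = model.reactions[rid]
        b = exchange_bounds.get(rid, (rxn.lower_bound, rxn.upper_bound))
        lb.append(b[0])
        ub.append(b[1])
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_reaction)] = 1.0
    return LinearProblem(
        c=c,
        A_eq=S.toarray(),
        b_eq=np.zeros(S.shape[0]),
        lb=np.asarray(lb, dtype=float),
        ub=np.asarray(ub, dtype=float),
        variables=list(rxn_ids),
    )


def _check_solution(problem: LinearProblem, x: np.ndarray) -> None:
    residual = np.abs(problem.A_eq @ x - problem.b_eq).max() if problem.A_eq.size else 0.0
    if residual > BALANCE_TOL:
        raise RuntimeError(f"steady-state residual {residual:.3g} exceeds tolerance")
    if ((x - problem.ub) > BALANCE_TOL).any() or ((problem.lb - x) > BALANCE_TOL).any():
        raise RuntimeError("solution violates flux bounds beyond tolerance")


def solve_fba(
    model: StrainModel,
    medium: Medium,
    objective_reaction: Optional[str] = None,
) -> FluxSolution:
    """Maximize a reaction flux (biomass by default) under a medium.

    Infeasibility and unboundedness are reported through the solution
    status, never raised.
    """
    problem = build_fba_problem(model, medium, objective_reaction)
    status, x, objective = solve_linear_problem(problem)
    if status is not SolverStatus.OPTIMAL:
        return FluxSolution(fluxes={}, objective_value=objective, status=status)
    _check_solution(problem, x)
    fluxes = {rid: float(v) for rid, v in zip(problem.variables, x)}
    return FluxSolution(fluxes=fluxes, objective_value=objective, status=status)


def _solve_with_exchange_override(model: StrainModel, lb_scale, closed: bool) -> float:
    """Biomass optimum with all exchanges fully open or uptake-closed."""
    bounds = {}
    for rxn in model.exchange_reactions:
        lo = 0.0 if closed else -OPEN_BOUND
        bounds[rxn.id] = (lo, OPEN_BOUND)
    problem = build_fba_problem(model, None, None, exchange_bounds=bounds)
    status, _x, objective = solve_linear_problem(problem)
    if status is SolverStatus.UNBOUNDED:
        return float("inf")
    if status is not SolverStatus.OPTIMAL:
        return 0.0
    return objective


def validate_strain_model(model: StrainModel, tolerance: float = FLUX_EPSILON) -> QCReport:
    """Report-only quality control.

    * open-exchange growth: the biomass optimum with every exchange fully
      open must exceed ``tolerance`` (a model that cannot grow on anything
      is broken);
    * leak check: with all exchange uptake closed the biomass optimum must
      not exceed ``tolerance`` (growth from nothing means mass is created);
    * elemental balance of every internal reaction whose metabolites all
      carry formulas; reactions missing formulas are listed as skipped.
    """
    report = QCReport()

    growth = _solve_with_exchange_override(model, OPEN_BOUND, closed=False)
    report.append(
        QCFinding(
            "open_exchange_growth",
            model.biomass_reaction.id,
            "PASS" if growth > tolerance else "FAIL",
            f"max biomass with open exchanges = {growth:.6g}",
        )
    )

    leak = _solve_with_exchange_override(model, OPEN_BOUND, closed=True)
    report.append(
        QCFinding(
            "closed_exchange_leak",
            model.biomass_reaction.id,
            "PASS" if leak <= tolerance else "FAIL",
            f"max biomass with uptake closed = {leak:.6g}",
        )
    )

    for rxn in model.reactions.values():
        if rxn.is_exchange or rxn.is_biomass:
            continue
        formulas = {m: model.metabolites[m].formula for m in rxn.stoichiometry}
        if any(f is None for f in formulas.values()):
            report.append(
                QCFinding("elemental_balance", rxn.id, "SKIP", "missing formula(s)")
            )
            continue
        totals: Dict[str, float] = {}
        for met_id, coef in rxn.stoichiometry.items():
            for element, count in parse_formula(formulas[met_id]).items():
                totals[element] = totals.get(element, 0.0) + coef * count
        imbalanced = {el: t for el, t in totals.items() if abs(t) > 1e-6}
        report.append(
            QCFinding(
                "elemental_balance",
                rxn.id,
                "FAIL" if imbalanced else "PASS",
                f"imbalance {imbalanced}" if imbalanced else "",
            )
        )
    return report


def strain_trait_summary(model: StrainModel, media: Sequence[Medium]) -> Dict[str, object]:
    """Counts plus biomass optimum per medium, flat enough for TSV export.

    The exchange-reaction count proxies the strain's resource-utilization
    spectrum; solver failures on a medium are recorded as the status
    string rather than aborting the batch.
    """
    record: Dict[str, object] = {
        "strain_id": model.strain_id,
        "n_reactions": len(model.reactions),
        "n_exchanges": len(model.exchange_reactions),
        "n_transports": len(model.transport_reactions),
        "n_metabolites": len(model.metabolites),
    }
    for medium in media:
        sol = solve_fba(model, medium)
        key = f"biomass[{medium.name}]"
        record[key] = sol.objective_value if sol.ok else sol.status.value
    return record
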