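"""Multi-strain community models over a shared extracellular pool.

Each member strain keeps its own namespaced internal network and bounds.
The strains' exchange fluxes meet in a community metabolite pool: for
every shared extracellular metabolite ``m`` the balance

    sum_k v_ex[m, k] + IP_m - EP_m = 0

must hold, where ``IP_m >= 0`` is the community import from the medium
(bounded by the available amount) and ``EP_m >= 0`` is export out of the
system (unbounded by default).  A secreted metabolite (positive exchange
flux) therefore either feeds a partner strain or leaves through ``EP``.

The community objective is a weighted sum of member biomass fluxes.
Four scenarios are supported:

* ``no_limitation`` — maximize sum_k c_k v_biomass_k with every member
  free to carry zero biomass;
* ``equal_abundance`` — all members grow at a common rate mu (hard
  coupling v_biomass_k = mu), maximize mu;
* ``defined_abundances`` — v_biomass_k = a_k mu with fixed composition
  a_k summing to 1, maximize mu;
* ``target_strain`` — maximize one member's biomass, allocating the
  community's resources exclusively to it.

Parsimonious solving (pFBA) is a two-stage lexicographic program: fix
the scenario optimum, then minimize the total community import
``sum_m IP_m`` (minimal nutrient uptake among the optima).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    Medium,
    Metabolite,
    ModelError,
    SolverStatus,
    StrainModel,
    is_inorganic,
    namespaced,
)
from .fba import (
    BALANCE_TOL,
    FLUX_EPSILON,
    LinearProblem,
    solve_linear_problem,
)

__all__ = [
    "CommunityModel",
    "CommunitySolution",
    "DepletionResult",
    "ObjectiveSpec",
    "PoolFlow",
    "assemble_community",
    "max_target_biomass_profile",
    "simulate_depletion",
    "solve_community",
    "solve_community_pfba",
    "total_import",
]

SCENARIOS = ("equal_abundance", "no_limitation", "target_strain", "defined_abundances")

#: finite stand-in for "unbounded" pool export, large against all toy fluxes
EXPORT_CAP = 1e6


@dataclass
class ObjectiveSpec:
    """Scenario selector with the weight/abundance vector it needs."""

    scenario: str
    weights: Optional[Dict[str, float]] = None
    abundances: Optional[Dict[str, float]] = None
    target: Optional[str] = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ModelError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "target_strain":
            if not self.target:
                raise ModelError("target_strain scenario requires a target")
            self.weights = {self.target: 1.0}
        if self.scenario == "defined_abundances":
            if not self.abundances:
                raise ModelError("defined_abundances requires abundances")
            total = sum(self.abundances.values())
            if any(a <= 0 for a in self.abundances.values()) or abs(total - 1.0) > 1e-9:
                raise ModelError("abundances must be positive and sum to 1")
        if self.weights is not None and any(w < 0 for w in self.weights.values()):
            raise ModelError("objective weights must be non-negative")

    # Convenience constructors -------------------------------------------
    @classmethod
    def no_limitation(cls, weights: Optional[Dict[str, float]] = None) -> "ObjectiveSpec":
        return cls("no_limitation", weights=weights)

    @classmethod
    def equal_abundance(cls) -> "ObjectiveSpec":
        return cls("equal_abundance")

    @classmethod
    def target_strain(cls, target: str) -> "ObjectiveSpec":
        return cls("target_strain", target=target)

    @classmethod
    def defined_abundances(cls, abundances: Dict[str, float]) -> "ObjectiveSpec":
        return cls("defined_abundances", abundances=dict(abundances))

    def resolve_weights(self, strain_ids: Sequence[str]) -> Dict[str, float]:
        if self.scenario == "target_strain":
            if self.target not in strain_ids:
                raise ModelError(f"unknown target strain {self.target!r}")
            return {k: (1.0 if k == self.target else 0.0) for k in strain_ids}
        weights = self.weights or {}
        unknown = sorted(set(weights) - set(strain_ids))
        if unknown:
            raise ModelError(f"weights name unknown strains {unknown}")
        return {k: weights.get(k, 1.0) for k in strain_ids}

    def resolve_abundances(self, strain_ids: Sequence[str]) -> Dict[str, float]:
        # equal_abundance couples every strain to the common growth value mu
        # itself (v_bio^k = mu, the per-strain biomass); defined_abundances
        # splits mu as a composition (v_bio^k = a^k mu, mu the total).
        if self.scenario == "equal_abundance":
            return {k: 1.0 for k in strain_ids}
        assert self.abundances is not None
        if set(self.abundances) != set(strain_ids):
            raise ModelError("abundances must cover exactly the community's strains")
        return dict(self.abundances)

    @property
    def coupled(self) -> bool:
        return self.scenario in ("equal_abundance", "defined_abundances")


@dataclass
class PoolFlow:
    imported: float
    exported: float
    per_strain: Dict[str, float]


@dataclass
class CommunitySolution:
    strain_biomass: Dict[str, float]
    fluxes: Dict[str, float]
    pool_flows: Dict[str, PoolFlow]
    objective_value: float
    status: SolverStatus
    scenario: ObjectiveSpec

    @property
    def ok(self) -> bool:
        return self.status is SolverStatus.OPTIMAL

    @property
    def total_biomass(self) -> float:
        return float(sum(self.strain_biomass.values()))

    def to_dict(self) -> Dict[str, object]:
        return {
            "scenario": self.scenario.scenario,
            "objective_value": self.objective_value,
            "status": self.status.value,
            "strain_biomass": dict(self.strain_biomass),
            "pool_flows": {
                m: {
                    "IP": pf.imported,
                    "EP": pf.exported,
                    "per_strain": dict(pf.per_strain),
                }
                for m, pf in self.pool_flows.items()
            },
        }


class CommunityModel:
    """K namespaced strains joined through a shared extracellular pool."""

    def __init__(
        self,
        strains: Sequence[StrainModel],
        medium: Medium,
        pool_import_bounds: Optional[Dict[str, float]] = None,
        pool_export_bounds: Optional[Dict[str, float]] = None,
    ) -> None:
        if not strains:
            raise ModelError("community needs at least one strain")
        ids = [s.strain_id for s in strains]
        if len(set(ids)) != len(ids):
            raise ModelError(f"duplicate strain ids in {ids}")
        for strain in strains:
            if not strain.exchange_reactions:
                raise ModelError(
                    f"strain {strain.strain_id!r} has no exchange reactions and "
                    "cannot interact with the pool"
                )
        self.strains: List[StrainModel] = list(strains)
        self.medium = medium
        shared: Dict[str, Metabolite] = {}
        for strain in self.strains:
            for rxn in strain.exchange_reactions:
                met_id = strain.exchange_metabolite(rxn.id)
                shared.setdefault(met_id, strain.metabolites[met_id])
        self.shared_metabolites: List[str] = sorted(shared)
        self._pool_metabolites = shared
        if pool_import_bounds is None:
            pool_import_bounds = {
                m: medium.amount_for(shared[m]) for m in self.shared_metabolites
            }
        self.pool_import_bounds: Dict[str, float] = dict(pool_import_bounds)
        self.pool_export_bounds: Dict[str, float] = dict(pool_export_bounds or {})

    @property
    def strain_ids(self) -> List[str]:
        return [s.strain_id for s in self.strains]

    def pool_metabolite(self, met_id: str) -> Metabolite:
        return self._pool_metabolites[met_id]

    def with_import_bounds(self, bounds: Dict[str, float]) -> "CommunityModel":
        merged = dict(self.pool_import_bounds)
        merged.update(bounds)
        return CommunityModel(
            self.strains, self.medium, merged, dict(self.pool_export_bounds)
        )

    # -- LP assembly -------------------------------------------------------
    def build_problem(self, objective: ObjectiveSpec) -> Tuple[LinearProblem, Dict[str, int]]:
        """Equality system: per-strain steady state, pool balances, and
        (for coupled scenarios) biomass-composition coupling rows."""
        variables: List[str] = []
        lb: List[float] = []
        ub: List[float] = []
        exchange_cols: Dict[str, List[Tuple[str, int]]] = {
            m: [] for m in self.shared_metabolites
        }
        biomass_col: Dict[str, int] = {}

        for strain in self.strains:
            for rid, rxn in strain.reactions.items():
                col = len(variables)
                variables.append(namespaced(strain.strain_id, rid))
                lb.append(rxn.lower_bound)
                ub.append(rxn.upper_bound)
                if rxn.is_biomass:
                    biomass_col[strain.strain_id] = col
                if rxn.is_exchange:
                    met_id = strain.exchange_metabolite(rid)
                    exchange_cols[met_id].append((strain.strain_id, col))

        ip_col: Dict[str, int] = {}
        ep_col: Dict[str, int] = {}
        for m in self.shared_metabolites:
            ip_col[m] = len(variables)
            variables.append(f"IP:{m}")
            lb.append(0.0)
            ub.append(max(0.0, self.pool_import_bounds.get(m, 0.0)))
            ep_col[m] = len(variables)
            variables.append(f"EP:{m}")
            lb.append(0.0)
            ub.append(self.pool_export_bounds.get(m, EXPORT_CAP))

        mu_col = -1
        if objective.coupled:
            mu_col = len(variables)
            variables.append("MU")
            lb.append(0.0)
            ub.append(np.inf)

        rows: List[np.ndarray] = []
        n = len(variables)

        # per-strain steady state
        offset = 0
        for strain in self.strains:
            S, _met_ids, rxn_ids = strain.stoichiometric_matrix()
            block = S.toarray()
            for i in range(block.shape[0]):
                row = np.zeros(n)
                row[offset : offset + len(rxn_ids)] = block[i]
                rows.append(row)
            offset += len(rxn_ids)

        # pool balances: sum_k v_ex + IP - EP = 0
        for m in self.shared_metabolites:
            row = np.zeros(n)
            for _sid, col in exchange_cols[m]:
                row[col] += 1.0
            row[ip_col[m]] = 1.0
            row[ep_col[m]] = -1.0
            rows.append(row)

        c = np.zeros(n)
        if objective.coupled:
            abundances = objective.resolve_abundances(self.strain_ids)
            for sid, a in abundances.items():
                row = np.zeros(n)
                row[biomass_col[sid]] = 1.0
                row[mu_col] = -a
                rows.append(row)
            c[mu_col] = 1.0
        else:
            weights = objective.resolve_weights(self.strain_ids)
            for sid, w in weights.items():
                c[biomass_col[sid]] = w

        A_eq = np.vstack(rows) if rows else np.zeros((0, n))
        problem = LinearProblem(
            c=c,
            A_eq=A_eq,
            b_eq=np.zeros(A_eq.shape[0]),
            lb=np.asarray(lb, dtype=float),
            ub=np.asarray(ub, dtype=float),
            variables=variables,
        )
        columns = {"mu": mu_col}
        columns.update({f"bio:{k}": v for k, v in biomass_col.items()})
        columns.update({f"ip:{m}": ip_col[m] for m in self.shared_metabolites})
        columns.update({f"ep:{m}": ep_col[m] for m in self.shared_metabolites})
        self._exchange_cols = exchange_cols
        return problem, columns

    def _package_solution(
        self,
        objective: ObjectiveSpec,
        problem: LinearProblem,
        columns: Dict[str, int],
        x: np.ndarray,
        objective_value: float,
    ) -> CommunitySolution:
        fluxes = {
            name: float(v)
            for name, v in zip(problem.variables, x)
            if not name.startswith(("IP:", "EP:")) and name != "MU"
        }
        strain_biomass = {
            sid: float(x[columns[f"bio:{sid}"]]) for sid in self.strain_ids
        }
        pool_flows = {}
        for m in self.shared_metabolites:
            per_strain = {
                sid: float(x[col]) for sid, col in self._exchange_cols[m]
            }
            pool_flows[m] = PoolFlow(
                imported=float(x[columns[f"ip:{m}"]]),
                exported=float(x[columns[f"ep:{m}"]]),
                per_strain=per_strain,
            )
        solution = CommunitySolution(
            strain_biomass=strain_biomass,
            fluxes=fluxes,
            pool_flows=pool_flows,
            objective_value=objective_value,
            status=SolverStatus.OPTIMAL,
            scenario=objective,
        )
        _assert_balances(self, solution)
        return solution

    def _zero_solution(self, objective: ObjectiveSpec) -> CommunitySolution:
        """All-zero fluxes: the biologically meaningful 'cannot grow' answer
        for coupled scenarios whose coupling admits no positive mu."""
        fluxes = {}
        for strain in self.strains:
            for rid in strain.reactions:
                fluxes[namespaced(strain.strain_id, rid)] = 0.0
        return CommunitySolution(
            strain_biomass={k: 0.0 for k in self.strain_ids},
            fluxes=fluxes,
            pool_flows={
                m: PoolFlow(0.0, 0.0, {}) for m in self.shared_metabolites
            },
            objective_value=0.0,
            status=SolverStatus.OPTIMAL,
            scenario=objective,
        )


def _assert_balances(model: CommunityModel, solution: CommunitySolution) -> None:
    """Universal post-condition: per-strain steady state and pool balance."""
    for strain in model.strains:
        totals: Dict[str, float] = {m: 0.0 for m in strain.metabolites}
        for rid, rxn in strain.reactions.items():
            v = solution.fluxes[namespaced(strain.strain_id, rid)]
            for met_id, coef in rxn.stoichiometry.items():
                totals[met_id] += coef * v
        worst = max((abs(t) for t in totals.values()), default=0.0)
        if worst > BALANCE_TOL:
            raise RuntimeError(
                f"strain {strain.strain_id!r} steady-state residual {worst:.3g}"
            )
    for m, pf in solution.pool_flows.items():
        residual = sum(pf.per_strain.values()) + pf.imported - pf.exported
        if abs(residual) > BALANCE_TOL:
            raise RuntimeError(f"pool balance residual {residual:.3g} for {m!r}")


def assemble_community(strains: Sequence[StrainModel], medium: Medium) -> CommunityModel:
    """Join strains through a shared pool; imports bounded by the medium."""
    return CommunityModel(strains, medium)


def solve_community(model: CommunityModel, objective: ObjectiveSpec) -> CommunitySolution:
    problem, columns = model.build_problem(objective)
    status, x, value = solve_linear_problem(problem)
    if status is SolverStatus.INFEASIBLE and objective.coupled:
        return model._zero_solution(objective)
    if status is not SolverStatus.OPTIMAL:
        return CommunitySolution(
            strain_biomass={k: float("nan") for k in model.strain_ids},
            fluxes={},
            pool_flows={},
            objective_value=value,
            status=status,
            scenario=objective,
        )
    return model._package_solution(objective, problem, columns, x, value)


def solve_community_pfba(
    model: CommunityModel,
    objective: ObjectiveSpec,
    mode: str = "import",
) -> CommunitySolution:
    """Two-stage lexicographic solve.

    Stage 1 fixes the scenario optimum z*; stage 2 minimizes the total
    community import sum_m IP_m ("minimal nutrient uptake", the default)
    or, with ``mode='total_flux'``, the classical sum of absolute fluxes.
    The returned solution attains z* within 1e-6 relative.
    """
    if mode not in ("import", "total_flux"):
        raise ModelError(f"unknown pFBA mode {mode!r}")
    stage1 = solve_community(model, objective)
    if not stage1.ok or not math.isfinite(stage1.objective_value):
        return stage1
    z_star = stage1.objective_value

    problem, columns = model.build_problem(objective)
    n = len(problem.variables)
    slack = 1e-9 + 1e-9 * abs(z_star)

    if mode == "import":
        c2 = np.zeros(n)
        for m in model.shared_metabolites:
            c2[columns[f"ip:{m}"]] = -1.0  # maximize -sum(IP)
        A_ub = -problem.c.reshape(1, -1)  # c.x >= z* - slack
        b_ub = np.array([-(z_star - slack)])
        stage2 = LinearProblem(
            c=c2, A_eq=problem.A_eq, b_eq=problem.b_eq,
            lb=problem.lb, ub=problem.ub, variables=problem.variables,
            A_ub=A_ub, b_ub=b_ub,
        )
        status, x, _ = solve_linear_problem(stage2)
        if status is not SolverStatus.OPTIMAL:  # pragma: no cover - safety net
            return stage1
        x_sol = x
    else:
        # classical pFBA: minimize sum |v| over strain reactions via t >= |v|
        flux_cols = [
            i for i, name in enumerate(problem.variables)
            if not name.startswith(("IP:", "EP:")) and name != "MU"
        ]
        m_aux = len(flux_cols)
        c2 = np.zeros(n + m_aux)
        c2[n:] = -1.0
        A_eq = np.hstack([problem.A_eq, np.zeros((problem.A_eq.shape[0], m_aux))])
        rows_ub = [np.concatenate([-problem.c, np.zeros(m_aux)])]
        b_ub = [-(z_star - slack)]
        for j, col in enumerate(flux_cols):
            row = np.zeros(n + m_aux)
            row[col] = 1.0
            row[n + j] = -1.0
            rows_ub.append(row)  # v - t <= 0
            b_ub.append(0.0)
            row = np.zeros(n + m_aux)
            row[col] = -1.0
            row[n + j] = -1.0
            rows_ub.append(row)  # -v - t <= 0
            b_ub.append(0.0)
        stage2 = LinearProblem(
            c=c2,
            A_eq=A_eq,
            b_eq=problem.b_eq,
            lb=np.concatenate([problem.lb, np.zeros(m_aux)]),
            ub=np.concatenate([problem.ub, np.full(m_aux, np.inf)]),
            variables=problem.variables + [f"T:{j}" for j in range(m_aux)],
            A_ub=np.vstack(rows_ub),
            b_ub=np.asarray(b_ub),
        )
        status, x, _ = solve_linear_problem(stage2)
        if status is not SolverStatus.OPTIMAL:  # pragma: no cover - safety net
            return stage1
        x_sol = x[:n]

    value = float(problem.c @ x_sol)
    return model._package_solution(objective, problem, columns, x_sol, value)


def total_import(solution: CommunitySolution) -> float:
    """Total community nutrient import sum_m IP_m."""
    return float(sum(pf.imported for pf in solution.pool_flows.values()))


# ---------------------------------------------------------------------------
# Finite-pool depletion
# ---------------------------------------------------------------------------

@dataclass
class DepletionStep:
    step: int
    time: float
    biomass_increment: Dict[str, float]
    remaining: Dict[str, float]


@dataclass
class DepletionResult:
    trajectory: List[DepletionStep]
    cumulative_biomass: Dict[str, float]
    growth_time: float
    stopped_because: str  # pool_exhausted | no_growth | max_steps

    @property
    def total_biomass(self) -> float:
        return float(sum(self.cumulative_biomass.values()))


def simulate_depletion(
    model: CommunityModel,
    objective: ObjectiveSpec,
    dt: float = 1.0,
    vmax: float = 10.0,
    max_steps: int = 200,
    epsilon: float = FLUX_EPSILON,
) -> DepletionResult:
    """Iterative finite-pool growth: the medium is a stock, not a rate.

    Per step, each pool import rate is capped at
    ``min(remaining/dt, vmax)``; the community is solved with pFBA; pools
    are decremented by net consumption and credited with net secretion
    (``(EP - IP) * dt``), so donated metabolites accumulate for partners
    between steps.  Stops when the step's total biomass increment falls
    below ``epsilon``, distinguishing pool exhaustion from intrinsic
    no-growth, or at ``max_steps``.  ``growth_time`` counts productive
    steps times ``dt``.
    """
    if dt <= 0:
        raise ModelError("dt must be positive")
    if vmax <= 0:
        raise ModelError("vmax must be positive")

    pools: Dict[str, float] = dict(model.pool_import_bounds)
    cumulative = {k: 0.0 for k in model.strain_ids}
    trajectory: List[DepletionStep] = []
    productive_steps = 0
    stopped_because = "max_steps"

    for step in range(1, max_steps + 1):
        rate_caps = {m: min(max(pools[m], 0.0) / dt, vmax) for m in pools}
        stepped = model.with_import_bounds(rate_caps)
        solution = solve_community_pfba(stepped, objective)
        increment = {
            k: (solution.strain_biomass.get(k, 0.0) * dt if solution.ok else 0.0)
            for k in model.strain_ids
        }
        total_increment = sum(increment.values())
        if total_increment < epsilon:
            organic_left = [
                amt
                for m, amt in pools.items()
                if not is_inorganic(model.pool_metabolite(m).formula)
            ]
            exhausted = all(a <= epsilon for a in organic_left)
            stopped_because = (
                "no_growth" if productive_steps == 0 or not exhausted else "pool_exhausted"
            )
            break
        for m, pf in solution.pool_flows.items():
            pools[m] = max(0.0, pools[m] + (pf.exported - pf.imported) * dt)
        for k, inc in increment.items():
            cumulative[k] += inc
        productive_steps += 1
        trajectory.append(
            DepletionStep(
                step=step,
                time=productive_steps * dt,
                biomass_increment=increment,
                remaining=dict(pools),
            )
        )

    return DepletionResult(
        trajectory=trajectory,
        cumulative_biomass=cumulative,
        growth_time=productive_steps * dt,
        stopped_because=stopped_because,
    )


def max_target_biomass_profile(
    model: CommunityModel,
    dt: float = 1.0,
    vmax: float = 10.0,
    max_steps: int = 200,
) -> Dict[str, Tuple[float, float]]:
    """Per strain: single-shot biomass and depletion growth time when the
    community's resources are allocated exclusively to that strain."""
    profile: Dict[str, Tuple[float, float]] = {}
    for sid in model.strain_ids:
        objective = ObjectiveSpec.target_strain(sid)
        try:
            shot = solve_community_pfba(model, objective)
            biomass = shot.strain_biomass.get(sid, 0.0) if shot.ok else float("nan")
            depletion = simulate_depletion(model, objective, dt, vmax, max_steps)
            profile[sid] = (biomass, depletion.growth_time)
        except RuntimeError:  # solver failure must not abort the profile
            profile[sid] = (float("nan"), float("nan"))
    return profile
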