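"""Combination screening, media series, sensitivity analysis, and PCI.

A screen enumerates strain subsets, solves each subset as a community
(pFBA) under a series of media, and tabulates per-member biomass.  The
media series mimics single- versus co-contamination: a fixed total
carbon budget split evenly over the first C carbon sources (C = 1, 2,
4, ...), with ammonium at 100 mmol/gDW and all carbon/nitrogen-free
inorganics at 1000 mmol/gDW.

The Potentiator Contribution Index quantifies the relative performance
gain of a Degrader+Helper+Potentiator consortium over its
Degrader+Helper baseline:

    PCI = (Perf(DHP) - Perf(DH)) / Perf(DH) * 100  [percent]
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .community import (
    ObjectiveSpec,
    assemble_community,
    simulate_depletion,
    solve_community_pfba,
)
from .core import Medium, ModelError, StrainModel, molecular_weight, parse_formula
from .fba import FLUX_EPSILON

__all__ = [
    "CombinationResult",
    "CarbonEquivalence",
    "ScreenConfig",
    "SensitivityResult",
    "build_media_series",
    "carbon_equivalence",
    "compute_pci",
    "default_perturbations",
    "enumerate_combinations",
    "results_to_frame",
    "run_screen",
    "sensitivity_analysis",
]

AMMONIUM_ID = "nh4"
AMMONIUM_AMOUNT = 100.0
GLUCOSE_FORMULA = "C6H12O6"


@dataclass
class ScreenConfig:
    strain_pool: Sequence[str]
    min_size: int
    max_size: int
    media: Sequence[Medium]
    scenarios: Sequence[str]
    seed: int = 0
    with_growth_time: bool = False
    dt: float = 1.0
    vmax: float = 10.0
    max_steps: int = 200

    def __post_init__(self) -> None:
        if not (1 <= self.min_size <= self.max_size <= len(self.strain_pool)):
            raise ModelError(
                f"invalid subset sizes {self.min_size}..{self.max_size} for a "
                f"pool of {len(self.strain_pool)}"
            )
        if not self.scenarios:
            raise ModelError("at least one scenario is required")
        if not self.media:
            raise ModelError("at least one medium is required")


@dataclass
class CombinationResult:
    members: Tuple[str, ...]
    medium_name: str
    scenario: str
    status: str
    total_biomass: float
    strain_biomass: Dict[str, float]
    growth_time: Optional[float] = None


def enumerate_combinations(
    pool: Union[int, Sequence[str]], min_size: int, max_size: int
) -> List[Tuple]:
    """All strain subsets of sizes min_size..max_size.

    Order is deterministic: by size, then lexicographic over the sorted
    pool.  ``pool`` may be a pool size (subsets of 0-based indices) or a
    sequence of strain ids.
    """
    items: Sequence = range(pool) if isinstance(pool, int) else sorted(pool)
    n = len(items)
    if not (1 <= min_size <= max_size <= n):
        raise ModelError(f"invalid subset sizes {min_size}..{max_size} for n={n}")
    out: List[Tuple] = []
    for size in range(min_size, max_size + 1):
        out.extend(itertools.combinations(items, size))
    return out


def build_media_series(
    carbon_sources: Sequence[str],
    total_carbon_budget: float,
    lengths: Optional[Sequence[int]] = None,
    ammonium_amount: float = AMMONIUM_AMOUNT,
) -> List[Medium]:
    """Media splitting one carbon budget across 1, 2, 4, ... sources.

    Each medium gives ``budget / C`` to each of the first C sources in the
    list, plus ammonium at 100 mmol/gDW; C/N-free inorganics are covered
    by the medium's default rule (1000 mmol/gDW).  The default lengths
    double (1, 2, 4, ...) up to the list length, always ending at the
    full list.
    """
    if not carbon_sources:
        raise ModelError("carbon source list must be non-empty")
    if total_carbon_budget <= 0:
        raise ModelError("carbon budget must be positive")
    n = len(carbon_sources)
    if lengths is None:
        lengths = []
        c = 1
        while c < n:
            lengths.append(c)
            c *= 2
        lengths.append(n)
    media = []
    for c in lengths:
        if not (1 <= c <= n):
            raise ModelError(f"invalid series length {c} for {n} sources")
        share = total_carbon_budget / c
        amounts = {met: share for met in carbon_sources[:c]}
        amounts[AMMONIUM_ID] = ammonium_amount
        media.append(Medium(name=f"C{c}", amounts=amounts))
    return media


def run_screen(
    config: ScreenConfig, models: Mapping[str, StrainModel]
) -> List[CombinationResult]:
    """Solve every (combination x medium x scenario) cell with pFBA.

    Strain order is canonicalized before enumeration so results are
    invariant to input ordering; solver failures are recorded in the
    result status, never raised.
    """
    missing = sorted(set(config.strain_pool) - set(models))
    if missing:
        raise ModelError(f"no model supplied for strain(s) {missing}")
    combos = enumerate_combinations(list(config.strain_pool), config.min_size, config.max_size)
    results: List[CombinationResult] = []
    for members in combos:
        strains = [models[sid] for sid in members]
        for medium in config.media:
            community = assemble_community(strains, medium)
            for scenario in config.scenarios:
                objective = _scenario_objective(scenario, members)
                try:
                    solution = solve_community_pfba(community, objective)
                except RuntimeError as exc:
                    results.append(
                        CombinationResult(
                            members=tuple(members),
                            medium_name=medium.name,
                            scenario=scenario,
                            status=f"error: {exc}",
                            total_biomass=float("nan"),
                            strain_biomass={},
                        )
                    )
                    continue
                growth_time = None
                if config.with_growth_time and solution.ok:
                    growth_time = simulate_depletion(
                        community, objective, config.dt, config.vmax, config.max_steps
                    ).growth_time
                results.append(
                    CombinationResult(
                        members=tuple(members),
                        medium_name=medium.name,
                        scenario=scenario,
                        status=solution.status.value,
                        total_biomass=solution.total_biomass if solution.ok else float("nan"),
                        strain_biomass=dict(solution.strain_biomass),
                        growth_time=growth_time,
                    )
                )
    return results


def _scenario_objective(scenario: str, members: Sequence[str]) -> ObjectiveSpec:
    if scenario == "no_limitation":
        return ObjectiveSpec.no_limitation()
    if scenario == "equal_abundance":
        return ObjectiveSpec.equal_abundance()
    if scenario.startswith("target:"):
        target = scenario.split(":", 1)[1]
        if target not in members:
            raise ModelError(f"target {target!r} not in combination {members}")
        return ObjectiveSpec.target_strain(target)
    raise ModelError(f"unknown screen scenario {scenario!r}")


def results_to_frame(
    results: Sequence[CombinationResult], strain_pool: Sequence[str]
) -> pd.DataFrame:
    """Fixed-order tabular view: members, medium, scenario, status,
    total_biomass, one biomass column per pool strain, growth_time."""
    pool = sorted(strain_pool)
    rows = []
    for r in results:
        row: Dict[str, object] = {
            "members": "+".join(r.members),
            "medium": r.medium_name,
            "scenario": r.scenario,
            "status": r.status,
            "total_biomass": r.total_biomass,
        }
        for sid in pool:
            row[f"biomass[{sid}]"] = r.strain_biomass.get(sid, float("nan"))
        row["growth_time"] = r.growth_time if r.growth_time is not None else float("nan")
        rows.append(row)
    columns = ["members", "medium", "scenario", "status", "total_biomass"]
    columns += [f"biomass[{sid}]" for sid in pool]
    columns += ["growth_time"]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    table: pd.DataFrame
    baseline_biomass: float
    baseline_defined: bool
    max_relative_change: Optional[float]


def default_perturbations(
    base_medium: Medium,
    carbon_sources: Sequence[str],
    fraction: float = 0.2,
) -> List[Tuple[str, Dict[str, float]]]:
    """+-20% on each single carbon source plus pairwise reallocations that
    preserve the total budget (amount-delta dictionaries)."""
    deltas: List[Tuple[str, Dict[str, float]]] = []
    present = [m for m in carbon_sources if base_medium.amounts.get(m, 0.0) > 0]
    for m in present:
        step = fraction * base_medium.amounts[m]
        deltas.append((f"{m}+{int(fraction * 100)}%", {m: step}))
        deltas.append((f"{m}-{int(fraction * 100)}%", {m: -step}))
    for a, b in itertools.combinations(present, 2):
        step = fraction * min(base_medium.amounts[a], base_medium.amounts[b])
        deltas.append((f"{a}->{b}", {a: -step, b: step}))
        deltas.append((f"{b}->{a}", {a: step, b: -step}))
    return deltas


def sensitivity_analysis(
    models: Mapping[str, StrainModel],
    combination: Sequence[str],
    base_medium: Medium,
    perturbations: Optional[Sequence[Tuple[str, Dict[str, float]]]] = None,
    scenario: str = "no_limitation",
    epsilon: float = FLUX_EPSILON,
) -> SensitivityResult:
    """Relative total-biomass change of one combination under medium deltas.

    relative change = |biomass_perturbed - biomass_base| / biomass_base.
    A baseline at or below ``epsilon`` is flagged undefined (no division).
    """
    members = sorted(combination)
    strains = [models[sid] for sid in members]
    objective = _scenario_objective(scenario, members)

    def total(medium: Medium) -> float:
        solution = solve_community_pfba(assemble_community(strains, medium), objective)
        return solution.total_biomass if solution.ok else float("nan")

    base = total(base_medium)
    defined = math.isfinite(base) and base > epsilon
    if perturbations is None:
        carbons = [m for m in base_medium.amounts if m != AMMONIUM_ID]
        perturbations = default_perturbations(base_medium, carbons)

    rows = []
    for label, delta in perturbations:
        amounts = dict(base_medium.amounts)
        for met, d in delta.items():
            amounts[met] = amounts.get(met, 0.0) + d
            if amounts[met] < -1e-12:
                raise ModelError(
                    f"perturbation {label!r} drives {met!r} below zero"
                )
            amounts[met] = max(0.0, amounts[met])
        perturbed = total(Medium(name=f"{base_medium.name}|{label}", amounts=amounts))
        rel = abs(perturbed - base) / base if defined else float("nan")
        rows.append({"perturbation": label, "total_biomass": perturbed,
                     "relative_change": rel})
    table = pd.DataFrame(rows, columns=["perturbation", "total_biomass", "relative_change"])
    max_rel = float(table["relative_change"].max()) if defined and len(table) else None
    return SensitivityResult(
        table=table,
        baseline_biomass=base,
        baseline_defined=defined,
        max_relative_change=max_rel,
    )


# ---------------------------------------------------------------------------
# PCI and carbon equivalence
# ---------------------------------------------------------------------------

def compute_pci(performance_dhp: float, performance_dh: float) -> float:
    """Potentiator Contribution Index, in percent.

    Relative gain of the D+H+P consortium over the D+H baseline; negative
    values mean the third member hurts performance.
    """
    if performance_dh <= 0:
        raise ModelError("PCI undefined for non-positive baseline")
    return (performance_dhp - performance_dh) / performance_dh * 100.0


@dataclass
class CarbonEquivalence:
    mol_carbon: float
    equivalent_glucose_mg: float
    per_compound_mol_carbon: Dict[str, float] = field(default_factory=dict)


def carbon_equivalence(
    compounds: Sequence[Tuple[str, float]], volume_l: float
) -> CarbonEquivalence:
    """Total mol C delivered by (formula, mg/L) compounds in a volume,
    and the glucose mass (mg) supplying the same molar carbon."""
    if volume_l <= 0:
        raise ModelError("volume must be positive")
    per_compound: Dict[str, float] = {}
    total = 0.0
    for formula, conc_mg_per_l in compounds:
        if conc_mg_per_l < 0:
            raise ModelError(f"negative concentration for {formula!r}")
        counts = parse_formula(formula)
        n_c = counts.get("C", 0)
        if n_c == 0:
            raise ModelError(f"compound {formula!r} contains no carbon")
        mw = molecular_weight(formula)
        mass_mg = conc_mg_per_l * volume_l
        mol_c = mass_mg * 1e-3 / mw * n_c
        per_compound[formula] = per_compound.get(formula, 0.0) + mol_c
        total += mol_c
    glucose_mw = molecular_weight(GLUCOSE_FORMULA)
    glucose_mg = total / 6.0 * glucose_mw * 1e3
    return CarbonEquivalence(
        mol_carbon=total,
        equivalent_glucose_mg=glucose_mg,
        per_compound_mol_carbon=per_compound,
    )
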