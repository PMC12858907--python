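"""Brute-force reference LP solver for small flux polytopes.

Enumerates every basic solution of

    max c.x   s.t.   A_eq x = 0,   lb <= x <= ub

by choosing which variables are free (solved from the equality system)
and fixing every other variable at one of its bounds.  A candidate with
a consistent, uniquely solvable equality system and all bounds satisfied
is a vertex of the polytope; for a feasible bounded LP the optimum is
attained at one of them.  Exponential in the number of variables, so
only suitable as an independent check on models with roughly a dozen
fluxes — which is exactly its job: validating the production solver on
generated toy models and communities.
"""

from __future__ import annotations

import itertools
from typing import Optional, Tuple

import numpy as np

__all__ = ["brute_force_lp_max", "oracle_fba", "oracle_community"]

#: finite stand-in for infinite bounds during enumeration
BIG_BOUND = 1e6


def brute_force_lp_max(
    c: np.ndarray,
    A_eq: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    feas_tol: float = 1e-7,
) -> Tuple[Optional[float], Optional[np.ndarray]]:
    """Best objective over all basic feasible solutions, or (None, None)
    when the polytope is empty.

    Assumes the LP is bounded: artificial stand-ins for infinite bounds
    are never used as vertex values (a finite-optimum vertex cannot sit
    on a bound the model does not actually have).
    """
    c = np.asarray(c, dtype=float)
    A_eq = np.asarray(A_eq, dtype=float)
    lb = np.where(np.isfinite(lb), lb, -BIG_BOUND).astype(float)
    ub = np.where(np.isfinite(ub), ub, BIG_BOUND).astype(float)
    n = len(c)
    rank = np.linalg.matrix_rank(A_eq) if A_eq.size else 0

    # candidate fixed values per variable: its real (non-artificial) bounds
    bound_choices = []
    for j in range(n):
        vals = []
        if lb[j] > -BIG_BOUND:
            vals.append(lb[j])
        if ub[j] < BIG_BOUND and ub[j] != lb[j]:
            vals.append(ub[j])
        bound_choices.append(vals or [lb[j]])

    best_val: Optional[float] = None
    best_x: Optional[np.ndarray] = None

    for free in itertools.combinations(range(n), rank):
        free = list(free)
        fixed = [j for j in range(n) if j not in free]
        A_free = A_eq[:, free] if A_eq.size else np.zeros((0, 0))
        if rank and np.linalg.matrix_rank(A_free) < rank:
            continue
        # all bound assignments for the fixed block, evaluated in one sweep
        combos = np.array(
            list(itertools.product(*(bound_choices[j] for j in fixed)))
        ).T  # (n_fixed, K)
        if combos.size == 0:
            combos = np.zeros((0, 1))
        K = combos.shape[1]
        X = np.empty((n, K))
        if fixed:
            X[fixed, :] = combos
        if rank:
            rhs = -A_eq[:, fixed] @ combos if fixed else np.zeros((A_eq.shape[0], K))
            sol, *_ = np.linalg.lstsq(A_free, rhs, rcond=None)
            X[free, :] = sol
            residual = np.abs(A_eq @ X).max(axis=0)
        else:
            residual = np.zeros(K)
        scale = np.maximum(1.0, np.abs(X).max(axis=0))
        feasible = (
            (residual <= feas_tol * scale)
            & ((X - ub[:, None]) <= feas_tol).all(axis=0)
            & ((lb[:, None] - X) <= feas_tol).all(axis=0)
        )
        if not feasible.any():
            continue
        values = c @ X
        values[~feasible] = -np.inf
        k = int(np.argmax(values))
        if best_val is None or values[k] > best_val:
            best_val, best_x = float(values[k]), X[:, k].copy()
    return best_val, best_x


def oracle_fba(model, medium, objective_reaction=None) -> Optional[float]:
    """Single-strain FBA optimum by exhaustive vertex enumeration."""
    from .fba import build_fba_problem

    problem = build_fba_problem(model, medium, objective_reaction)
    value, _x = brute_force_lp_max(problem.c, problem.A_eq, problem.lb, problem.ub)
    return value


def oracle_community(model, objective) -> Optional[float]:
    """Community scenario optimum by exhaustive vertex enumeration."""
    problem, _columns = model.build_problem(objective)
    value, _x = brute_force_lp_max(problem.c, problem.A_eq, problem.lb, problem.ub)
    return value
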