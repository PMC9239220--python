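"""Independent brute-force oracles for cross-checking the solvers.

These deliberately avoid the implementation's formulations: the FBA oracle
enumerates polytope vertices instead of calling an LP on the same model,
and the GIMME oracle enumerates sign labelings of the penalized reversible
reactions, solving one plain (unsplit) LP per orthant.  Both are only
tractable on tiny networks, which is the point.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

from ymcflux.model import MetabolicModel


def fba_vertex_oracle(
    model: MetabolicModel, objective: str, sense: str = "max"
) -> float:
    """Optimize a reaction flux by exhaustive vertex enumeration.

    Vertices of {S v = 0, lb <= v <= ub} are intersections of the equality
    subspace with n - rank(S) active bound hyperplanes; every candidate is
    solved as a square linear system and screened for feasibility.
    """
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    n_active = n - rank
    rxn_index = model.reaction_ids.index(objective)

    best = None
    for subset in itertools.combinations(range(n), n_active):
        for sides in itertools.product((0, 1), repeat=n_active):
            rows = np.zeros((n_active, n))
            rhs = np.zeros(n_active)
            for row, (j, side) in enumerate(zip(subset, sides)):
                rows[row, j] = 1.0
                rhs[row] = ub[j] if side else lb[j]
            A = np.vstack([S, rows])
            b = np.concatenate([np.zeros(S.shape[0]), rhs])
            solution, residuals, rank_a, _ = np.linalg.lstsq(A, b, rcond=None)
            if rank_a < n:
                continue  # not a unique intersection point
            if np.abs(A @ solution - b).max() > 1e-8:
                continue
            if np.any(solution < lb - 1e-8) or np.any(solution > ub + 1e-8):
                continue
            value = solution[rxn_index]
            if best is None:
                best = value
            best = max(best, value) if sense == "max" else min(best, value)
    if best is None:
        raise ValueError("no feasible vertex found (model infeasible?)")
    return float(best)


def gimme_inconsistency_oracle(
    model: MetabolicModel,
    penalties: dict[str, float],
    objective_floor: float,
) -> float:
    """min sum_j c_j |v_j| by enumerating orthants of penalized reversible fluxes.

    Within a fixed sign labeling the objective is linear, so each labeling is
    one plain LP in v (no flux splitting); the oracle returns the minimum
    over all labelings.
    """
    rxn_ids = model.reaction_ids
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    lb, ub = lb.copy(), ub.copy()
    obj_index = rxn_ids.index(model.objective_reaction)
    lb[obj_index] = max(lb[obj_index], objective_floor)

    c_pen = np.array([penalties.get(r, 0.0) for r in rxn_ids])
    ambiguous = [
        j for j in range(len(rxn_ids)) if c_pen[j] > 0 and lb[j] < 0 < ub[j]
    ]
    best = None
    for signs in itertools.product((1.0, -1.0), repeat=len(ambiguous)):
        lo, hi = lb.copy(), ub.copy()
        cost = c_pen * np.where(lb >= 0, 1.0, np.where(ub <= 0, -1.0, 1.0))
        for j, sign in zip(ambiguous, signs):
            cost[j] = c_pen[j] * sign
            if sign > 0:
                lo[j] = 0.0
            else:
                hi[j] = 0.0
        result = linprog(
            cost, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lo, hi)),
            method="highs",
        )
        if result.status == 2:
            continue
        if not result.success:
            continue
        value = float(result.fun)
        best = value if best is None else min(best, value)
    if best is None:
        raise ValueError("all orthant LPs infeasible")
    return best
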