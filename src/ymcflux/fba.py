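"""Flux balance analysis: the linear-program primitive.

FBA optimizes a single reaction flux subject to steady-state mass balance
``S v = 0`` and flux bounds ``lb <= v <= ub``.  The LP is handed to the
HiGHS solver through :func:`scipy.optimize.linprog`; infeasibility and
unboundedness are surfaced as explicit package exceptions.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.optimize import linprog

from .errors import InfeasibleError, UnboundedError
from .model import FluxVector, MetabolicModel


def solve_lp(
    c: np.ndarray,
    A_eq: Optional[np.ndarray] = None,
    b_eq: Optional[np.ndarray] = None,
    A_ub: Optional[np.ndarray] = None,
    b_ub: Optional[np.ndarray] = None,
    bounds: Optional[list[tuple[float, float]]] = None,
    context: str = "LP",
) -> np.ndarray:
    """Minimize ``c @ x`` with HiGHS; returns the solution vector.

    Raises :class:`InfeasibleError` / :class:`UnboundedError` with a message
    naming ``context`` so callers can attribute failures.
    """
    result = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs"
    )
    if result.status == 2:
        raise InfeasibleError(f"{context}: problem is infeasible")
    if result.status == 3:
        raise UnboundedError(f"{context}: objective is unbounded")
    if not result.success:  # pragma: no cover - solver-internal failures
        raise RuntimeError(f"{context}: solver failed with status {result.status}: {result.message}")
    return np.asarray(result.x, dtype=float)


def solve_fba(
    model: MetabolicModel,
    objective: Optional[str] = None,
    sense: str = "max",
) -> FluxVector:
    """Optimize the flux of one reaction at steady state.

    Parameters
    ----------
    model:
        The metabolic model supplying ``S`` and the bounds.
    objective:
        Reaction id to optimize; defaults to the model's objective reaction.
    sense:
        ``"max"`` or ``"min"``.

    Returns a :class:`FluxVector` whose ``objective_value`` is the optimum;
    the vector satisfies conservation and bounds (asserted via ``check``).
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    objective = objective or model.objective_reaction
    rxn_ids = model.reaction_ids
    if objective not in rxn_ids:
        raise KeyError(f"no reaction {objective!r} in model {model.id!r}")

    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(rxn_ids)
    c = np.zeros(n)
    c[rxn_ids.index(objective)] = -1.0 if sense == "max" else 1.0

    x = solve_lp(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        context=f"FBA({sense} {objective}) on model {model.id!r}",
    )
    flux = FluxVector(
        fluxes=dict(zip(rxn_ids, map(float, x))),
        objective_value=float(x[rxn_ids.index(objective)]),
        total_flux=float(np.abs(x).sum()),
    )
    flux.check(model)
    return flux
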