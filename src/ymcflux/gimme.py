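"""GIMME context-specific model extraction and combinatory models.

GIMME (Gene Inactivity Moderated by Metabolism and Expression) reconciles a
metabolic model with condition data: reactions whose mapped data value
``x_j`` falls below a threshold ``T`` are penalized in proportion to their
distance from it (``c_j = T - x_j``), and the LP

    min sum_j c_j |v_j|   s.t.  S v = 0,  lb <= v <= ub,  v_obj >= f * V_opt

finds the flux distribution that uses "inactive" reactions as little as
possible while still attaining a fraction ``f`` of the model's optimal
objective.  The optimal penalty sum is the *inconsistency score* I*: zero
means the data and the objective are perfectly compatible.

Because the LP often has alternate optima, a canonicalization step rescales
the solution deterministically: with the penalty sum fixed at I*, total
absolute flux is minimized.  The context-specific model then keeps every
reaction that is either above threshold, unmapped (no data is not evidence
of absence), or carrying flux in the canonical solution; everything else is
removed along with orphaned metabolites and genes.

Combinatory models merge the activity calls of two data channels: a binary
vector marks reactions active in *either* channel (union) or *both*
(intersection) and is fed back through GIMME with threshold 0.5, so that
mass balance can override the data where pruning would break the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import config
from .errors import InfeasibleError
from .fba import solve_fba, solve_lp
from .model import FluxVector, MetabolicModel
from .omics import ReactionDataVector, percentile_threshold


@dataclass
class GimmeConfig:
    """Tunables of the GIMME extraction.

    ``threshold`` is an absolute reaction-value cutoff; when ``None`` it is
    computed as the ``threshold_percentile`` of the mapped values of the
    input vector (default: 25th percentile).  ``objective_fraction`` is the
    minimum allowed ratio of context objective flux to the generic optimum.
    """

    threshold: Optional[float] = None
    threshold_percentile: float = 25.0
    objective_fraction: float = 0.5
    activity_tolerance: float = config.ZERO_FLUX_TOL

    def __post_init__(self):
        if not 0 < self.objective_fraction <= 1:
            raise ValueError(
                f"objective_fraction must be in (0, 1], got {self.objective_fraction}"
            )


@dataclass
class GimmeResult:
    flux: FluxVector
    inconsistency_score: float
    active_reactions: set[str]
    context_model: MetabolicModel
    v_opt: float
    threshold: float
    penalties: dict[str, float] = field(default_factory=dict)


def _penalties(data: ReactionDataVector, threshold: float) -> dict[str, float]:
    """c_j = max(0, T - x_j) for mapped reactions; unmapped carry no penalty."""
    return {
        rxn: max(0.0, threshold - value)
        for rxn, value in data.values.items()
        if value is not None
    }


def _split_lp_matrices(model: MetabolicModel):
    """Equality system for variables [v, v+, v-]: S v = 0 and v - v+ + v- = 0."""
    S = model.stoichiometric_matrix()
    m, n = S.shape
    A_eq = np.zeros((m + n, 3 * n))
    A_eq[:m, :n] = S
    A_eq[m:, :n] = np.eye(n)
    A_eq[m:, n : 2 * n] = -np.eye(n)
    A_eq[m:, 2 * n :] = np.eye(n)
    return A_eq, np.zeros(m + n)


def gimme(
    model: MetabolicModel,
    data: ReactionDataVector,
    cfg: Optional[GimmeConfig] = None,
) -> GimmeResult:
    """Extract a context-specific model from reaction-level data.

    Three solves: (1) FBA for the generic optimum ``V_opt``; (2) the GIMME
    LP minimizing the penalty-weighted total flux subject to the objective
    floor ``f * V_opt``, giving the inconsistency score I*; (3) with the
    penalty sum pinned at I*, total absolute flux is minimized to obtain a
    deterministic representative flux (alternate-optima canonicalization).
    """
    cfg = cfg or GimmeConfig()
    rxn_ids = model.reaction_ids
    n = len(rxn_ids)
    unknown = set(data.values) - set(rxn_ids)
    if unknown:
        raise KeyError(f"data names unknown reactions {sorted(unknown)}")

    threshold = (
        cfg.threshold
        if cfg.threshold is not None
        else percentile_threshold(data.values.values(), cfg.threshold_percentile)
    )
    penalties = _penalties(data, threshold)
    c_pen = np.array([penalties.get(r, 0.0) for r in rxn_ids])

    v_opt = solve_fba(model).objective_value
    if v_opt <= 0:
        raise InfeasibleError(
            f"model {model.id!r} has non-positive optimum V_opt={v_opt:.6g}; GIMME needs V_opt > 0"
        )
    floor = cfg.objective_fraction * v_opt

    lb, ub = model.bounds_arrays()
    obj_index = rxn_ids.index(model.objective_reaction)
    lb = lb.copy()
    lb[obj_index] = max(lb[obj_index], floor)
    if lb[obj_index] > ub[obj_index] + config.FEASIBILITY_TOL:
        raise InfeasibleError(
            f"objective-fraction floor {floor:.6g} exceeds the objective upper bound"
        )
    cap = np.maximum(np.abs(lb), np.abs(ub))
    bounds = (
        list(zip(lb, ub))
        + [(0.0, float(c)) for c in cap]
        + [(0.0, float(c)) for c in cap]
    )
    A_eq, b_eq = _split_lp_matrices(model)

    # Step 2: minimize penalty-weighted total flux.
    cost = np.concatenate([np.zeros(n), c_pen, c_pen])
    x = solve_lp(cost, A_eq=A_eq, b_eq=b_eq, bounds=bounds, context="GIMME step 2")
    inconsistency = float(cost @ x)

    # Step 3: canonicalize among alternate optima by minimizing total |v|.
    A_ub = cost.reshape(1, -1)
    b_ub = np.array([inconsistency + 1e-9])
    total_cost = np.concatenate([np.zeros(n), np.ones(n), np.ones(n)])
    x = solve_lp(
        total_cost, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=bounds,
        context="GIMME step 3",
    )
    v = x[:n]
    flux = FluxVector(
        fluxes=dict(zip(rxn_ids, map(float, v))),
        objective_value=float(v[obj_index]),
        total_flux=float(np.abs(v).sum()),
    )
    flux.check(model)

    active = {
        rxn
        for j, rxn in enumerate(rxn_ids)
        if data.values[rxn] is None                      # unmapped: never pruned
        or data.values[rxn] >= threshold                 # supported by the data
        or abs(v[j]) > cfg.activity_tolerance            # required by metabolism
    }
    context = model.subset(active, model_id=f"{model.id}_{data.channel}_{data.sample}".rstrip("_"))
    return GimmeResult(
        flux=flux,
        inconsistency_score=inconsistency,
        active_reactions=active,
        context_model=context,
        v_opt=v_opt,
        threshold=float(threshold),
        penalties=penalties,
    )


def combine_activity(
    a: set[str],
    b: set[str],
    mode: str,
    model: MetabolicModel,
) -> ReactionDataVector:
    """Binary reaction vector over the whole model: union or intersection of two active sets."""
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")
    rxn_ids = set(model.reaction_ids)
    unknown = (set(a) | set(b)) - rxn_ids
    if unknown:
        raise KeyError(f"active sets name unknown reactions {sorted(unknown)}")
    combined = (set(a) | set(b)) if mode == "union" else (set(a) & set(b))
    values = {r: (1.0 if r in combined else 0.0) for r in model.reaction_ids}
    return ReactionDataVector(values=values, sample=mode, channel="binary")


def contextualize_binary(
    model: MetabolicModel,
    binary: ReactionDataVector,
    objective_fraction: float = 0.5,
) -> GimmeResult:
    """GIMME on a 0/1 activity vector with threshold 0.5.

    Reactions marked 0 receive penalty 0.5 and are pruned where possible;
    reactions marked 1 are kept; mass balance can keep a 0-marked reaction
    if the objective floor requires it.
    """
    bad = {r: v for r, v in binary.values.items() if v is not None and v not in (0.0, 1.0)}
    if bad:
        raise ValueError(f"binary vector has non-binary values: {bad}")
    cfg = GimmeConfig(threshold=0.5, objective_fraction=objective_fraction)
    return gimme(model, binary, cfg)
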