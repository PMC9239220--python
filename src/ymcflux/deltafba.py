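"""Differential flux inference between two conditions (ΔFBA-style).

Given signed gene-level log2 fold changes with significance q-values, the
significant genes (q < alpha) are mapped onto reactions through GPR rules
(min over ``and``, max over ``or``), producing a signed reaction-level
direction set D.  The flux *difference* vector Δv between the two
conditions is then inferred in two steps:

1. **Consistency maximization (MILP).**  Δv lives in the box
   ``[lb - ub, ub - lb]`` and satisfies ``S Δv = 0`` (both conditions are at
   steady state, so their difference is too).  A binary y_j per reaction in
   D enforces, when set, a flux change of at least ε in the direction of
   the data via big-M linking; the number of satisfied reactions N = Σ y_j
   is maximized.

2. **Inconsistency minimization (QP).**  With the optimal assignment y*
   fixed (a deterministic, convex restriction of "Σ y_j = N*"), the squared
   flux change over the reactions *outside* D is minimized, yielding a
   unique Δv on the unchanged part of the network.  An L1 variant is
   available for callers that prefer a pure-LP pipeline.

Reactions with |Δv_j| >= ε form the altered set; the union of their GPR
genes is the terminal gene-level output (downstream enrichment is the
caller's business).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import Bounds, LinearConstraint, milp, minimize

from . import config
from .errors import OmicsError
from .fba import solve_lp
from .gpr import evaluate_gpr
from .model import MetabolicModel
from .omics import OmicsTable, ReactionDataVector


@dataclass
class DifferentialGeneTable:
    """Gene-level differential results: signed log2 fold change + q-value."""

    data: pd.DataFrame  # index gene_id, columns log2fc, qvalue

    def __post_init__(self):
        missing = {"log2fc", "qvalue"} - set(self.data.columns)
        if missing:
            raise OmicsError(f"differential table missing columns {sorted(missing)}")
        self.data = self.data.astype({"log2fc": float, "qvalue": float})
        if self.data.index.has_duplicates:
            dup = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise OmicsError(f"duplicate gene ids in differential table: {dup}")
        q = self.data["qvalue"]
        if ((q < 0) | (q > 1)).any():
            bad = self.data.index[(q < 0) | (q > 1)][0]
            raise OmicsError(f"q-value outside [0, 1] for gene {bad!r}")
        if not np.isfinite(self.data["log2fc"]).all():
            bad = self.data.index[~np.isfinite(self.data["log2fc"])][0]
            raise OmicsError(f"non-finite fold change for gene {bad!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    def to_tsv(self, path: Union[str, Path]) -> None:
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def read_differential(path: Union[str, Path]) -> DifferentialGeneTable:
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return DifferentialGeneTable(frame)


def filter_significant(diff: DifferentialGeneTable, alpha: float = 0.01) -> DifferentialGeneTable:
    """Keep genes with q < alpha; q >= alpha (boundary included) is discarded."""
    kept = diff.data[diff.data["qvalue"] < alpha].copy()
    return DifferentialGeneTable(kept)


def map_differential_to_reactions(
    model: MetabolicModel, diff: DifferentialGeneTable
) -> ReactionDataVector:
    """Map signed fold changes onto reactions with the min/AND, max/OR rule."""
    gene_values = {g: float(v) for g, v in diff.data["log2fc"].items()}
    values = {rxn.id: evaluate_gpr(rxn.gpr, gene_values) for rxn in model.reactions}
    return ReactionDataVector(values=values, sample="diff", channel="foldchange")


@dataclass
class DeltaFbaConfig:
    """ε is used both as the consistency margin (step 1) and, via
    ``epsilon_altered``, as the altered-set cutoff; the two share the 0.1
    default but can be set independently."""

    epsilon: float = 0.1
    alpha: float = 0.01
    big_M: Optional[float] = None  # default: 2 * max bound range of the model
    epsilon_altered: Optional[float] = None
    objective: str = "l2"  # "l2" (default) or "l1" inconsistency minimization

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.objective not in ("l2", "l1"):
            raise ValueError(f"objective must be 'l2' or 'l1', got {self.objective!r}")

    @property
    def altered_cutoff(self) -> float:
        return self.epsilon if self.epsilon_altered is None else self.epsilon_altered


@dataclass
class DeltaFluxResult:
    delta_v: dict[str, float]
    consistent_reactions: set[str]
    n_consistent: int
    altered_reactions: set[str]
    altered_genes: set[str]
    direction_set: dict[str, float] = field(default_factory=dict)  # D: reaction -> signed w

    def as_array(self, reaction_ids) -> np.ndarray:
        return np.array([self.delta_v[r] for r in reaction_ids], dtype=float)


def _check_conservation(model: MetabolicModel, d: np.ndarray) -> None:
    residual = np.abs(model.stoichiometric_matrix() @ d).max(initial=0.0)
    if residual > config.MASS_BALANCE_TOL:
        raise AssertionError(
            f"Δv mass-balance residual {residual:.3e} exceeds {config.MASS_BALANCE_TOL:.0e}"
        )


def delta_fba(
    model: MetabolicModel,
    diff_reactions: ReactionDataVector,
    cfg: Optional[DeltaFbaConfig] = None,
) -> DeltaFluxResult:
    """Infer the flux-difference vector Δv from mapped signed fold changes.

    ``diff_reactions`` should carry values only for the significant set D
    (map the output of :func:`filter_significant`); zero fold changes carry
    no direction and are ignored.
    """
    cfg = cfg or DeltaFbaConfig()
    rxn_ids = model.reaction_ids
    n = len(rxn_ids)
    lb, ub = model.bounds_arrays()
    d_lo, d_hi = lb - ub, ub - lb
    S = model.stoichiometric_matrix()

    direction = {
        r: float(w)
        for r, w in diff_reactions.values.items()
        if w is not None and w != 0.0
    }
    D = [r for r in rxn_ids if r in direction]
    k = len(D)
    signs = np.array([np.sign(direction[r]) for r in D])
    D_index = np.array([rxn_ids.index(r) for r in D], dtype=int)

    if k == 0:
        delta = {r: 0.0 for r in rxn_ids}
        return DeltaFluxResult(
            delta_v=delta,
            consistent_reactions=set(),
            n_consistent=0,
            altered_reactions=set(),
            altered_genes=set(),
            direction_set={},
        )

    big_M = cfg.big_M if cfg.big_M is not None else 2.0 * float(np.max(ub - lb))

    # Step 1 (MILP): maximize the number of direction-consistent reactions.
    c = np.concatenate([np.zeros(n), -np.ones(k)])
    A_link = np.zeros((k, n + k))
    for row, (j, s) in enumerate(zip(D_index, signs)):
        A_link[row, j] = s
        A_link[row, n + row] = -big_M
    constraints = [
        LinearConstraint(np.hstack([S, np.zeros((S.shape[0], k))]), 0.0, 0.0),
        LinearConstraint(A_link, cfg.epsilon - big_M, np.inf),
    ]
    integrality = np.concatenate([np.zeros(n), np.ones(k)])
    var_bounds = Bounds(
        np.concatenate([d_lo, np.zeros(k)]), np.concatenate([d_hi, np.ones(k)])
    )
    result = milp(c, constraints=constraints, integrality=integrality, bounds=var_bounds)
    if not result.success:
        raise RuntimeError(f"ΔFBA step-1 MILP failed: {result.message}")
    y_star = np.round(result.x[n:]).astype(int)
    n_star = int(y_star.sum())
    d0 = result.x[:n]

    # Step 2: minimize inconsistency on reactions outside D, holding y*.
    satisfied = [(j, s) for (j, s), y in zip(zip(D_index, signs), y_star) if y == 1]
    mask = np.ones(n)
    mask[D_index] = 0.0  # inconsistency counted outside the direction set only
    d = _minimize_inconsistency(
        S, d_lo, d_hi, satisfied, mask, cfg, x0=d0
    )

    _check_conservation(model, d)
    cutoff = cfg.altered_cutoff
    delta = dict(zip(rxn_ids, map(float, d)))
    consistent = {D[i] for i in range(k) if y_star[i] == 1}
    altered = {r for r, dv in delta.items() if abs(dv) >= cutoff - config.ZERO_FLUX_TOL}
    altered_genes: set[str] = set()
    for r in altered:
        altered_genes |= model.reaction(r).genes
    return DeltaFluxResult(
        delta_v=delta,
        consistent_reactions=consistent,
        n_consistent=n_star,
        altered_reactions=altered,
        altered_genes=altered_genes,
        direction_set=direction,
    )


def _minimize_inconsistency(S, d_lo, d_hi, satisfied, mask, cfg, x0):
    """Step-2 solve: L2 (QP via trust-constr) or L1 (LP via flux splitting)."""
    n = S.shape[1]
    if cfg.objective == "l1":
        # variables [d, t] with t >= |d_j| for j outside D; min sum(mask * t)
        A_eq = np.hstack([S, np.zeros((S.shape[0], n))])
        rows = []
        for j in range(n):
            up = np.zeros(2 * n); up[j] = 1.0; up[n + j] = -1.0
            dn = np.zeros(2 * n); dn[j] = -1.0; dn[n + j] = -1.0
            rows += [up, dn]
        A_ub = [np.array(rows)]
        b_ub = [np.zeros(2 * n)]
        for j, s in satisfied:
            row = np.zeros(2 * n)
            row[j] = -s
            A_ub.append(row.reshape(1, -1))
            b_ub.append(np.array([-cfg.epsilon]))
        span = float(np.max(np.abs(np.concatenate([d_lo, d_hi]))))
        bounds = list(zip(d_lo, d_hi)) + [(0.0, span)] * n
        x = solve_lp(
            np.concatenate([np.zeros(n), mask]),
            A_eq=A_eq, b_eq=np.zeros(S.shape[0]),
            A_ub=np.vstack(A_ub), b_ub=np.concatenate(b_ub),
            bounds=bounds, context="ΔFBA step 2 (L1)",
        )
        return x[:n]

    A_sign = np.zeros((len(satisfied), n))
    for row, (j, s) in enumerate(satisfied):
        A_sign[row, j] = s

    # Work in the null space of S: d = N t keeps S d = 0 exact by
    # construction and shrinks the QP to n - rank(S) dimensions (the
    # stoichiometric matrix is rank-deficient whenever cofactor pairs are
    # conserved, which stalls equality-constrained solvers).
    N = null_space(S)
    if N.shape[1] == 0:
        return np.zeros(n)
    t0 = N.T @ x0  # orthonormal basis: projection of the MILP point

    P = np.diag(np.sqrt(mask)) @ N
    H = 2.0 * (P.T @ P)
    objective = lambda t: float(t @ (H @ t)) / 2.0
    jac = lambda t: H @ t

    # inequalities G t >= h: sign consistency and the Δv box
    G = np.vstack([A_sign @ N, N, -N])
    h = np.concatenate([np.full(len(satisfied), cfg.epsilon), d_lo, -d_hi])
    cons = [{"type": "ineq", "fun": lambda t: G @ t - h, "jac": lambda t: G}]

    result = minimize(
        objective, x0=t0, jac=jac, constraints=cons,
        method="SLSQP", options={"ftol": 1e-14, "maxiter": 1000},
    )
    t = result.x
    if not result.success or (G @ t < h - 1e-7).any():
        result = minimize(
            objective, x0=t0, jac=jac, hess=lambda t: H,
            constraints=[LinearConstraint(G, h, np.inf)],
            method="trust-constr",
            options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 5000, "verbose": 0},
        )
        if not result.success and result.status not in (1, 2):  # pragma: no cover
            raise RuntimeError(f"ΔFBA step-2 QP did not converge: {result.message}")
        t = result.x
    return np.asarray(N @ t, dtype=float)


def altered_pathway_genes(result: DeltaFluxResult, model: MetabolicModel) -> list[str]:
    """Sorted union of GPR leaf genes over the altered reactions."""
    genes: set[str] = set()
    for r in result.altered_reactions:
        genes |= model.reaction(r).genes
    return sorted(genes)
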