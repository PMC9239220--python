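"""Two-stage FBA and the per-phase contextualization pipeline.

The flux predictions use a two-stage optimization: first growth is
maximized (FBA), then, with growth constrained to stay within a slack of
its optimum ((1 - slack) * V_opt <= V_growth <= V_opt), the sum of absolute
fluxes is minimized — a parsimonious-FBA-style second objective that
narrows the solution space to an economical flux routing.  By default the
second objective covers intracellular reactions only (exchange fluxes are
excluded); a config flag includes them.

``run_phase`` is the per-phase orchestration: it maps each data channel
onto reactions, extracts a context model per channel via GIMME, builds
intersection and union combinatory models from the channels' activity
calls, and runs the two-stage FBA on all four context models plus the
generic model under the phase's medium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from . import config
from .fba import solve_fba, solve_lp
from .gimme import GimmeConfig, GimmeResult, combine_activity, contextualize_binary, gimme
from .model import FluxVector, MetabolicModel
from .omics import OmicsTable, map_sample_to_reactions

#: The four context-model variants built per phase, plus the generic parent.
MODEL_VARIANTS = ("generic", "rna", "atac", "intersection", "union")


@dataclass
class SimulationConfig:
    """Medium and second-stage settings for the flux simulations.

    ``medium`` maps uptake-exchange ids to their maximum uptake rate
    (mmol/gDW/h); uptake exchanges *not* listed are closed, secretion
    exchanges are left open.  ``glucose_uptake`` is the conventional
    carbon-limited default applied to ``glucose_exchange`` when a medium is
    built for a model.
    """

    glucose_uptake: float = 1.45
    growth_slack: float = 0.1
    medium: Optional[dict[str, float]] = None
    include_exchanges_in_total: bool = False

    def __post_init__(self):
        if self.glucose_uptake <= 0:
            raise ValueError(f"glucose_uptake must be > 0, got {self.glucose_uptake}")
        if not 0 <= self.growth_slack < 1:
            raise ValueError(f"growth_slack must be in [0, 1), got {self.growth_slack}")


def apply_medium(model: MetabolicModel, cfg: SimulationConfig) -> MetabolicModel:
    """Constrain uptake exchanges to the configured medium.

    Uptake exchanges are single-metabolite reactions that *produce* their
    metabolite (sources); their upper bounds are set to the medium's uptake
    limits (0 when absent).  Secretion exchanges (sinks) are untouched.
    """
    if cfg.medium is None:
        return model
    unknown = set(cfg.medium) - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"medium names unknown exchanges {sorted(unknown)}")
    bounds = {}
    for rxn in model.reactions:
        if not rxn.is_exchange:
            continue
        coefficient = next(iter(rxn.stoichiometry.values()))
        if coefficient <= 0:
            continue  # secretion/sink: leave open
        limit = cfg.medium.get(rxn.id, 0.0)
        bounds[rxn.id] = (rxn.lower_bound, float(limit))
    return model.with_bounds(bounds)


@dataclass
class TwoStepResult:
    flux: FluxVector
    v_opt: float
    total_flux: float          # sum |v| over all reactions
    internal_flux: float       # sum |v| over the stage-2 objective's reactions


def two_step_fba(model: MetabolicModel, cfg: Optional[SimulationConfig] = None) -> TwoStepResult:
    """Growth maximization followed by total-flux minimization at near-optimal growth."""
    cfg = cfg or SimulationConfig()
    model = apply_medium(model, cfg)
    rxn_ids = model.reaction_ids
    n = len(rxn_ids)
    obj_index = rxn_ids.index(model.objective_reaction)

    stage1 = solve_fba(model)
    v_opt = stage1.objective_value
    if v_opt <= config.ZERO_FLUX_TOL:
        warnings.warn(
            f"model {model.id!r}: V_opt = {v_opt:.3g} <= 0; stage 2 skipped",
            stacklevel=2,
        )
        lb, ub = model.bounds_arrays()
        if np.all(lb <= 0) and np.all(ub >= 0):
            zero = FluxVector({r: 0.0 for r in rxn_ids}, 0.0, 0.0)
            zero.check(model)
            return TwoStepResult(zero, v_opt, 0.0, 0.0)
        return TwoStepResult(stage1, v_opt, stage1.total_flux or 0.0, 0.0)

    lb, ub = model.bounds_arrays()
    lb, ub = lb.copy(), ub.copy()
    lb[obj_index] = max(lb[obj_index], (1.0 - cfg.growth_slack) * v_opt)
    ub[obj_index] = min(ub[obj_index], v_opt)

    weights = np.array(
        [
            1.0 if (cfg.include_exchanges_in_total or not rxn.is_exchange) else 0.0
            for rxn in model.reactions
        ]
    )
    S = model.stoichiometric_matrix()
    m = S.shape[0]
    A_eq = np.zeros((m + n, 3 * n))
    A_eq[:m, :n] = S
    A_eq[m:, :n] = np.eye(n)
    A_eq[m:, n : 2 * n] = -np.eye(n)
    A_eq[m:, 2 * n :] = np.eye(n)
    cap = np.maximum(np.abs(lb), np.abs(ub))
    bounds = (
        list(zip(lb, ub))
        + [(0.0, float(c)) for c in cap]
        + [(0.0, float(c)) for c in cap]
    )
    cost = np.concatenate([np.zeros(n), weights, weights])
    x = solve_lp(
        cost, A_eq=A_eq, b_eq=np.zeros(m + n), bounds=bounds,
        context=f"two-step FBA stage 2 on {model.id!r}",
    )
    v = x[:n]
    flux = FluxVector(
        fluxes=dict(zip(rxn_ids, map(float, v))),
        objective_value=float(v[obj_index]),
        total_flux=float(np.abs(v).sum()),
    )
    flux.check(model)
    return TwoStepResult(
        flux=flux,
        v_opt=float(v_opt),
        total_flux=float(np.abs(v).sum()),
        internal_flux=float(weights @ np.abs(v)),
    )


@dataclass
class PhaseModels:
    """Per-phase outputs: the five model variants, their fluxes and counts."""

    phase: str
    models: dict[str, MetabolicModel]
    fluxes: dict[str, FluxVector]
    results: dict[str, TwoStepResult]
    counts: dict[str, dict[str, int]]
    gimme_results: dict[str, GimmeResult] = field(default_factory=dict)


def run_phase(
    model: MetabolicModel,
    rna: OmicsTable,
    atac: OmicsTable,
    phase_sample: str,
    gimme_cfg: Optional[GimmeConfig] = None,
    sim_cfg: Optional[SimulationConfig] = None,
    phase: Optional[str] = None,
) -> PhaseModels:
    """Build the four context models for one phase and predict their fluxes.

    ``phase_sample`` must be a column of both omics tables (typically the
    replicate-averaged time point).  The phase medium in ``sim_cfg`` is
    applied *before* contextualization, so the GIMME objective floor and the
    flux predictions see the same environment.
    """
    gimme_cfg = gimme_cfg or GimmeConfig()
    sim_cfg = sim_cfg or SimulationConfig()
    phase = phase or phase_sample
    base = apply_medium(model, sim_cfg)

    channel_results: dict[str, GimmeResult] = {}
    for channel, table in (("rna", rna), ("atac", atac)):
        vector = map_sample_to_reactions(base, table, phase_sample, channel=channel)
        channel_results[channel] = gimme(base, vector, gimme_cfg)

    active_rna = channel_results["rna"].active_reactions
    active_atac = channel_results["atac"].active_reactions
    for mode in ("intersection", "union"):
        binary = combine_activity(active_atac, active_rna, mode, base)
        channel_results[mode] = contextualize_binary(
            base, binary, objective_fraction=gimme_cfg.objective_fraction
        )

    models = {"generic": base}
    for name in ("rna", "atac", "intersection", "union"):
        models[name] = channel_results[name].context_model

    results = {name: two_step_fba(m, sim_cfg) for name, m in models.items()}
    return PhaseModels(
        phase=phase,
        models=models,
        fluxes={name: r.flux for name, r in results.items()},
        results=results,
        counts={name: m.counts() for name, m in models.items()},
        gimme_results=channel_results,
    )
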