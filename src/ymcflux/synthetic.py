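"""Synthetic study generator: toy networks, omics, differentials, fluxes.

Everything the analysis consumes is generated here with known ground truth,
emulating a cycling yeast culture profiled by two gene-level assays:

* a mass-balanced central-carbon toy network (glycolysis-, TCA-, pentose-
  phosphate-, storage- and fermentation-like modules) with GPR rules,
  a biomass objective carrying the growth-associated maintenance (GAM) ATP
  cost, and a fixed non-growth maintenance (NGAM) reaction;
* phase-structured gene activity: each metabolic-cycle phase switches whole
  modules on or off; active genes sit ``activity_fold`` above inactive ones
  on average, and two replicate measurements per phase are drawn per
  channel with lognormal noise — a low-noise channel emulating chromatin
  accessibility (ATAC-seq-like) and a higher-noise channel emulating
  expression (RNA-seq-like), sharing the same ground-truth activity;
* gene-level differential tables with planted significance;
* noisy "measured" fluxes derived from the ground-truth flux solution of
  each phase's submodel, emulating a 13C-MFA reference set.

The network additionally plants a never-active *bypass* module: one-step
shortcuts that are stoichiometrically equivalent to the multi-step
glycolysis and TCA routes.  Parsimonious FBA prefers these shortcuts
whenever they survive in a model, so a context-extraction method earns its
keep exactly by pruning them — without such decoy routes the generic model
would already predict the true fluxes and data integration could never
improve on it.

All outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .deltafba import DifferentialGeneTable
from .evaluation import MeasuredFluxTable
from .gpr import parse_gpr
from .model import DEFAULT_GAM, DEFAULT_NGAM, FluxVector, MetabolicModel, Metabolite, Reaction
from .omics import OmicsTable, average_replicates
from .pipeline import SimulationConfig, TwoStepResult, two_step_fba

PHASES = ("earlyRC", "midOX", "lateRB")

#: Pathway modules in build order; the first three form the growth backbone.
MODULES = ("glycolysis", "tca", "ppp", "storage", "fermentation")

_DEFAULT_PHASE_DESIGN = {
    "earlyRC": frozenset({"glycolysis", "tca", "ppp", "storage"}),
    "midOX": frozenset({"glycolysis", "tca", "ppp"}),
    "lateRB": frozenset({"glycolysis", "tca", "ppp", "fermentation"}),
}

#: Per-phase oxygen availability: the proliferation phase is O2-limited so
#: its ground truth must ferment; the others respire freely.
_DEFAULT_O2 = {"earlyRC": 10.0, "midOX": 10.0, "lateRB": 1.0}


@dataclass
class SyntheticSpec:
    """Study conditions of the synthetic experiment."""

    seed: int = 0
    n_pathway_modules: int = 5
    phase_design: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(_DEFAULT_PHASE_DESIGN)
    )
    activity_fold: float = 8.0        # ratio of active to inactive gene means
    noise_sigma_atac: float = 0.15    # log2-scale noise, accessibility channel
    noise_sigma_rna: float = 0.45     # log2-scale noise, expression channel
    flux_noise_frac: float = 0.05     # relative noise on measured fluxes
    replicates: int = 2
    base_log2_mean: float = 5.0       # mean of per-gene baseline abundance (log2)
    base_log2_sd: float = 0.5         # gene-to-gene spread of baselines (log2)
    glucose_uptake: float = 1.45      # mmol/gDW/h, carbon-limited default
    o2_uptake: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_O2))
    #: Per-module shifts of the gene baseline (log2).  Fermentative enzymes
    #: are constitutively among the most abundant yeast proteins, so their
    #: genes sit above the genome-wide baseline even when the pathway is off.
    module_baseline_offset: dict[str, float] = field(
        default_factory=lambda: {"fermentation": 1.0}
    )

    def __post_init__(self):
        if not 3 <= self.n_pathway_modules <= len(MODULES):
            raise ValueError(
                f"n_pathway_modules must be in [3, {len(MODULES)}] "
                f"(the backbone {MODULES[:3]} is required), got {self.n_pathway_modules}"
            )
        if self.activity_fold <= 1:
            raise ValueError(f"activity_fold must exceed 1, got {self.activity_fold}")
        for name in ("noise_sigma_atac", "noise_sigma_rna", "flux_noise_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        enabled = set(MODULES[: self.n_pathway_modules])
        self.phase_design = {
            phase: frozenset(m for m in modules if m in enabled)
            for phase, modules in self.phase_design.items()
        }
        for phase, modules in self.phase_design.items():
            if not {"glycolysis", "tca", "ppp"} <= modules:
                raise ValueError(
                    f"phase {phase!r} must keep the growth backbone active, got {sorted(modules)}"
                )

    @property
    def phases(self) -> list[str]:
        return list(self.phase_design)

    def phase_samples(self, phase: str) -> list[str]:
        return [f"{phase}_r{i + 1}" for i in range(self.replicates)]

    def medium(self, phase: str) -> dict[str, float]:
        return {"EX_glc": self.glucose_uptake, "EX_o2": self.o2_uptake[phase]}

    def simulation_config(self, phase: str) -> SimulationConfig:
        return SimulationConfig(glucose_uptake=self.glucose_uptake, medium=self.medium(phase))


# ---------------------------------------------------------------------------
# Toy network
# ---------------------------------------------------------------------------

# (id, stoichiometry, (lb, ub), gpr, module)  —  module None = unmapped backbone
_NETWORK = [
    # exchanges / maintenance (unmapped: never prunable by data)
    ("EX_glc", {"glc_e": 1}, (0, 1.45), "", None),
    ("EX_o2", {"o2_c": 1}, (0, 10), "", None),
    ("EX_co2", {"co2_c": -1}, (0, 1000), "", None),
    ("EX_etoh", {"etoh_c": -1}, (0, 1000), "", None),
    ("ATPM", {"atp_c": -1, "adp_c": 1}, (DEFAULT_NGAM, DEFAULT_NGAM), "", None),
    # biomass: precursor demands + GAM-scale ATP hydrolysis, growth objective
    (
        "BIOMASS",
        {
            "pyr_c": -0.7,
            "r5p_c": -0.2,
            "accoa_c": -0.25,
            "nadph_c": -0.5,
            "nadp_c": 0.5,
            "atp_c": -DEFAULT_GAM,
            "adp_c": DEFAULT_GAM,
        },
        (0, 1000),
        "",
        None,
    ),
    # glycolysis-like module
    ("GLT", {"glc_e": -1, "glc_c": 1}, (0, 10), "gGLT1 or gGLT2", "glycolysis"),
    ("HEX", {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1}, (0, 10), "gHEX1", "glycolysis"),
    ("PGI", {"g6p_c": -1, "f6p_c": 1}, (-10, 10), "gPGI1", "glycolysis"),
    ("PFK", {"f6p_c": -1, "atp_c": -1, "fdp_c": 1, "adp_c": 1}, (0, 10), "gPFK1", "glycolysis"),
    ("ALD", {"fdp_c": -1, "t3p_c": 2}, (0, 10), "gALD1", "glycolysis"),
    (
        "PYK",
        {"t3p_c": -1, "nad_c": -1, "adp_c": -2, "pyr_c": 1, "nadh_c": 1, "atp_c": 2},
        (0, 20),
        "gPYK1 and gPYK2",
        "glycolysis",
    ),
    # TCA-like module (lumped three-step oxidation + oxidative phosphorylation)
    (
        "PDH",
        {"pyr_c": -1, "nad_c": -1, "accoa_c": 1, "co2_c": 1, "nadh_c": 1},
        (0, 20),
        "gPDH1",
        "tca",
    ),
    ("TCA1", {"accoa_c": -1, "nad_c": -1, "aki_c": 1, "nadh_c": 1}, (0, 20), "gTCA1", "tca"),
    ("TCA2", {"aki_c": -1, "nad_c": -1, "suc_c": 1, "co2_c": 1, "nadh_c": 1}, (0, 20), "gTCA2", "tca"),
    (
        "TCA3",
        {"suc_c": -1, "nad_c": -2, "adp_c": -1, "co2_c": 1, "nadh_c": 2, "atp_c": 1},
        (0, 20),
        "gTCA3",
        "tca",
    ),
    (
        "OXP",
        {"nadh_c": -2, "o2_c": -1, "adp_c": -4, "nad_c": 2, "atp_c": 4},
        (0, 40),
        "gOXP1 or gOXP2",
        "tca",
    ),
    # pentose-phosphate-like module (NADPH + pentose supply)
    (
        "PPP1",
        {"g6p_c": -1, "nadp_c": -2, "ru5p_c": 1, "co2_c": 1, "nadph_c": 2},
        (0, 10),
        "gPPP1",
        "ppp",
    ),
    ("PPP2", {"ru5p_c": -1, "r5p_c": 1}, (0, 10), "gPPP2", "ppp"),
    # non-oxidative branch: returns surplus pentose to glycolysis (3 C5 -> 2 C6 + C3)
    ("TKL", {"r5p_c": -3, "f6p_c": 2, "t3p_c": 1}, (0, 10), "gTKL1", "ppp"),
    # storage module (carbohydrate charging/mobilization cycle)
    ("STO1", {"g6p_c": -1, "atp_c": -1, "sto_c": 1, "adp_c": 1}, (0, 10), "gSTO1", "storage"),
    ("STO2", {"sto_c": -1, "g6p_c": 1}, (0, 10), "gSTO2", "storage"),
    # fermentation module
    ("PDC", {"pyr_c": -1, "acald_c": 1, "co2_c": 1}, (0, 20), "gPDC1", "fermentation"),
    (
        "ADH",
        {"acald_c": -1, "nadh_c": -1, "etoh_c": 1, "nad_c": 1},
        (0, 20),
        "gADH1 or gADH2",
        "fermentation",
    ),
    # bypass module: stoichiometrically equivalent one-step shortcuts, never
    # active in any phase design — the decoy routes context extraction must prune
    (
        "GLYB",
        {"glc_c": -1, "adp_c": -2, "nad_c": -2, "pyr_c": 2, "atp_c": 2, "nadh_c": 2},
        (0, 10),
        "gGLYB1",
        "bypass",
    ),
    (
        "TCAB",
        {"accoa_c": -1, "nad_c": -4, "adp_c": -1, "co2_c": 2, "nadh_c": 4, "atp_c": 1},
        (0, 20),
        "gTCAB1",
        "bypass",
    ),
]

_COMPARTMENTS = {"e": "extracellular", "c": "cytosol"}


def make_toy_network(spec: Optional[SyntheticSpec] = None) -> MetabolicModel:
    """Build the toy central-carbon network for the given study spec.

    Module selection follows ``spec.n_pathway_modules`` (the three backbone
    modules are mandatory); the bypass decoys are always present.  The model
    is feasible with a strictly positive growth optimum under the default
    medium of every phase.
    """
    spec = spec or SyntheticSpec()
    enabled = set(MODULES[: spec.n_pathway_modules]) | {"bypass", None}
    rows = [row for row in _NETWORK if row[4] in enabled]
    met_ids = sorted({m for _, stoich, _, _, _ in rows for m in stoich})
    metabolites = [
        Metabolite(id=m, name=m.rsplit("_", 1)[0], compartment=_COMPARTMENTS[m.rsplit("_", 1)[1]])
        for m in met_ids
    ]
    reactions = [
        Reaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=float(lo),
            upper_bound=float(hi),
            gpr=parse_gpr(rule),
            subsystem=module,
        )
        for rid, stoich, (lo, hi), rule, module in rows
    ]
    return MetabolicModel(
        id="toy_ymc",
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction="BIOMASS",
        gam=DEFAULT_GAM,
        ngam=DEFAULT_NGAM,
    )


def reaction_modules(model: MetabolicModel) -> dict[str, Optional[str]]:
    """Reaction id -> module tag (None for unmapped backbone reactions)."""
    return {r.id: r.subsystem for r in model.reactions}


def gene_modules(model: MetabolicModel) -> dict[str, str]:
    """Gene id -> module of the (unique) module its reactions belong to."""
    out: dict[str, str] = {}
    for rxn in model.reactions:
        if rxn.subsystem is None:
            continue
        for gene in rxn.genes:
            out[gene] = rxn.subsystem
    return out


def central_reactions(model: MetabolicModel) -> list[str]:
    """The central-carbon reactions a flux-measurement study would report.

    All reactions of the metabolic pathway modules except the storage cycle
    (which carries no steady-state net flux) and the bypass decoys (model
    constructs, not biochemistry a tracer study would quantify), plus the
    four environment exchanges.
    """
    keep_modules = {"glycolysis", "tca", "ppp", "fermentation"}
    out = [r.id for r in model.reactions if r.subsystem in keep_modules]
    out += [r.id for r in model.reactions if r.id in ("EX_glc", "EX_o2", "EX_co2", "EX_etoh")]
    return out


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Planted truth of one synthetic study."""

    active_reactions: dict[str, set[str]]     # phase -> active reaction ids (incl. unmapped)
    true_flux: dict[str, FluxVector]          # phase -> two-stage FBA flux on the submodel
    true_results: dict[str, TwoStepResult]
    gene_module: dict[str, str]
    active_genes: dict[str, set[str]]         # phase -> genes of active modules


def ground_truth(model: MetabolicModel, spec: SyntheticSpec) -> GroundTruth:
    """Per-phase active sets and noiseless two-stage-FBA flux solutions."""
    modules = reaction_modules(model)
    gene_module = gene_modules(model)
    active_reactions: dict[str, set[str]] = {}
    active_genes: dict[str, set[str]] = {}
    true_flux: dict[str, FluxVector] = {}
    true_results: dict[str, TwoStepResult] = {}
    for phase, active_modules in spec.phase_design.items():
        active = {
            rid for rid, module in modules.items() if module is None or module in active_modules
        }
        submodel = model.subset(active, model_id=f"{model.id}_{phase}_truth")
        result = two_step_fba(submodel, spec.simulation_config(phase))
        active_reactions[phase] = active
        active_genes[phase] = {g for g, m in gene_module.items() if m in active_modules}
        true_flux[phase] = result.flux
        true_results[phase] = result
    return GroundTruth(
        active_reactions=active_reactions,
        true_flux=true_flux,
        true_results=true_results,
        gene_module=gene_module,
        active_genes=active_genes,
    )


# ---------------------------------------------------------------------------
# Omics simulation
# ---------------------------------------------------------------------------


def _gene_baselines(model: MetabolicModel, spec: SyntheticSpec) -> pd.Series:
    rng = np.random.default_rng([spec.seed, 1])
    genes = model.genes
    gene_module = gene_modules(model)
    offsets = np.array(
        [spec.module_baseline_offset.get(gene_module.get(g, ""), 0.0) for g in genes]
    )
    return pd.Series(
        spec.base_log2_mean + offsets + spec.base_log2_sd * rng.standard_normal(len(genes)),
        index=genes,
    )


def simulate_omics(
    model: MetabolicModel, spec: SyntheticSpec
) -> tuple[OmicsTable, OmicsTable]:
    """Draw (rna, atac) gene x sample tables with planted module activity.

    Gene g in phase p has log2 mean ``base_g + log2(fold)/2`` when its
    module is active and ``base_g - log2(fold)/2`` when inactive; each of
    the per-phase replicates adds channel-specific Gaussian noise on the
    log2 scale.  Both channels share baselines and activity (the planted
    biology); they differ only in noise level.
    """
    gene_module = gene_modules(model)
    genes = model.genes
    baselines = _gene_baselines(model, spec)
    half_gap = np.log2(spec.activity_fold) / 2.0
    columns = [s for phase in spec.phases for s in spec.phase_samples(phase)]

    tables = {}
    for stream, (channel, sigma) in enumerate(
        (("rna", spec.noise_sigma_rna), ("atac", spec.noise_sigma_atac))
    ):
        rng = np.random.default_rng([spec.seed, 2 + stream])
        data = {}
        for phase in spec.phases:
            active_modules = spec.phase_design[phase]
            mu = np.array(
                [
                    baselines[g]
                    + (half_gap if gene_module[g] in active_modules else -half_gap)
                    for g in genes
                ]
            )
            for sample in spec.phase_samples(phase):
                data[sample] = 2.0 ** (mu + sigma * rng.standard_normal(len(genes)))
        tables[channel] = OmicsTable(pd.DataFrame(data, index=genes)[columns])
    return tables["rna"], tables["atac"]


def phase_means(table: OmicsTable, spec: SyntheticSpec) -> OmicsTable:
    """Replicate-averaged table with one column per phase (raw-scale means)."""
    return average_replicates(
        table, {phase: spec.phase_samples(phase) for phase in spec.phases}
    )


def simulate_differential(
    model: MetabolicModel,
    spec: SyntheticSpec,
    phase_a: str,
    phase_b: str,
    channel: str = "atac",
) -> DifferentialGeneTable:
    """Gene-level differential table for phase_b relative to phase_a.

    log2 fold change is the difference of replicate-mean log2 values;
    q-values are planted: 0.001 for genes whose module activity differs
    between the phases, 0.5 otherwise.
    """
    rna, atac = simulate_omics(model, spec)
    table = {"rna": rna, "atac": atac}[channel]
    gene_module = gene_modules(model)
    log2 = np.log2(table.data)
    mean_a = log2[spec.phase_samples(phase_a)].mean(axis=1)
    mean_b = log2[spec.phase_samples(phase_b)].mean(axis=1)
    design_a, design_b = spec.phase_design[phase_a], spec.phase_design[phase_b]
    qvalues = [
        0.001 if (gene_module[g] in design_a) != (gene_module[g] in design_b) else 0.5
        for g in table.genes
    ]
    frame = pd.DataFrame(
        {"log2fc": (mean_b - mean_a).to_numpy(), "qvalue": qvalues}, index=table.genes
    )
    return DifferentialGeneTable(frame)


def simulate_measured_fluxes(
    model: MetabolicModel,
    truth: GroundTruth,
    phase: str,
    spec: SyntheticSpec,
    reactions: Optional[Sequence[str]] = None,
) -> MeasuredFluxTable:
    """Noisy measured fluxes for one phase (13C-MFA-style reference set).

    measured = true + Normal(0, flux_noise_frac * |true| + 0.01) over the
    central-carbon reactions by default.
    """
    if reactions is None:
        reactions = central_reactions(model)
    phase_index = spec.phases.index(phase)
    rng = np.random.default_rng([spec.seed, 4, phase_index])
    flux = truth.true_flux[phase]
    measured = {}
    for rid in reactions:
        true = flux.fluxes.get(rid, 0.0)  # pruned-in-truth reactions carry zero
        sd = spec.flux_noise_frac * abs(true) + (0.01 if spec.flux_noise_frac > 0 else 0.0)
        measured[rid] = float(true + sd * rng.standard_normal())
    return MeasuredFluxTable(measured)


# ---------------------------------------------------------------------------
# Small random networks (for solver cross-checks)
# ---------------------------------------------------------------------------


def make_random_network(seed: int, max_reactions: int = 8) -> MetabolicModel:
    """A small random feasible network with a positive objective optimum.

    A source -> chain -> sink backbone guarantees feasibility; extra random
    conversions (some reversible, some parallel to backbone edges) create
    alternate routes so that flux-routing optimizations have real choices.
    Used by brute-force solver cross-checks on networks of <= 8 reactions.
    """
    rng = np.random.default_rng([seed, 99])
    n_mets = int(rng.integers(2, 5))
    mets = [f"M{i}" for i in range(n_mets)]
    reactions = [
        Reaction(id="EX_in", stoichiometry={mets[0]: 1}, lower_bound=0,
                 upper_bound=float(rng.uniform(4, 12))),
    ]
    for i in range(n_mets - 1):
        reactions.append(
            Reaction(
                id=f"C{i}",
                stoichiometry={mets[i]: -1, mets[i + 1]: 1},
                lower_bound=0,
                upper_bound=float(rng.uniform(4, 12)),
            )
        )
    reactions.append(
        Reaction(id="OBJ", stoichiometry={mets[-1]: -1}, lower_bound=0, upper_bound=1000.0)
    )
    extra = int(rng.integers(0, max_reactions - len(reactions) + 1))
    for e in range(extra):
        i, j = rng.choice(n_mets, size=2, replace=False)
        ub = float(rng.uniform(2, 10))
        reversible = bool(rng.random() < 0.25)
        reactions.append(
            Reaction(
                id=f"R{e}",
                stoichiometry={mets[i]: -1.0, mets[j]: 1.0},
                lower_bound=-ub if reversible else 0.0,
                upper_bound=ub,
            )
        )
    return MetabolicModel(
        id=f"random_{seed}",
        metabolites=[Metabolite(id=m) for m in mets],
        reactions=reactions,
        objective_reaction="OBJ",
    )
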