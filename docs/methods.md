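# Methods

This package implements a chain of constraint-based analyses for
integrating gene-level omics into a metabolic network model, and a
synthetic-study generator that exercises the chain end to end with known
ground truth.  This note documents the models, the parameters that matter,
the numerical choices, and what the synthetic studies do and do not show.

## Flux balance analysis and the two-stage simulation

A metabolic model is a stoichiometric matrix `S` (m metabolites × n
reactions), flux bounds `lb_j ≤ v_j ≤ ub_j` (mmol/gDW/h), and a biomass
objective.  FBA solves

    max v_growth   s.t.   S v = 0,   lb ≤ v ≤ ub.

Flux predictions use a two-stage program: stage 1 computes the growth
optimum `V_opt`; stage 2 constrains `(1 − slack)·V_opt ≤ v_growth ≤ V_opt`
(default slack 0.1) and minimizes `Σ_j |v_j|` — a parsimonious-FBA-style
secondary objective that collapses alternate optima onto an economical
routing.  Absolute values are handled by exact flux splitting
(`v = v⁺ − v⁻`, `v± ≥ 0`, equality enforced in the LP).  By default the
stage-2 sum covers intracellular reactions only; exchange fluxes can be
included with `SimulationConfig(include_exchanges_in_total=True)`.  The
"total flux" recorded on results always sums over all reactions, whatever
the objective scope, so solution equivalence classes are verifiable.

Reversible reactions are encoded by `lb < 0` in the model file; splitting
is purely a solver-layer detail.  Growth-associated maintenance (GAM,
default 55.3 mmol ATP/gDW) appears as ATP-hydrolysis stoichiometry inside
the biomass reaction; non-growth-associated maintenance (NGAM, default
0.7 mmol ATP/gDW/h) is a dedicated reaction with `lb = ub = ngam`.  The
NGAM reaction carries no gene rule, so no data-driven extraction can prune
it — the sanest resolution of how a hard maintenance constraint should
interact with model pruning.

The medium is a mapping from uptake-exchange ids to maximal uptake rates;
uptake exchanges not listed are closed, secretion exchanges stay open.
Uptake exchanges are written as sources (positive flux imports the
metabolite).  The conventional carbon limit is a glucose uptake of
1.45 mmol/gDW/h.

## GPR mapping

Gene-protein-reaction rules are boolean trees (`and` = complex subunits,
`or` = isozymes; `and` binds tighter than `or`).  Quantitative gene values
map onto a reaction as min over `and` and max over `or`.  Unmeasured genes
are skipped at their parent node rather than propagated as failures; a
rule with no measured gene at all yields an explicit *unmapped* marker.
This matches common practice when a data set covers only part of a model's
gene complement.

## GIMME context extraction

Given mapped reaction values `x_j` and a threshold `T`, penalties are
`c_j = max(0, T − x_j)` (zero for unmapped reactions), and the LP

    min Σ_j c_j |v_j|   s.t.  S v = 0,  bounds,  v_obj ≥ f·V_opt

yields the inconsistency score `I*`.  Defaults: `T` = 25th percentile of
the sample's mapped reaction values (linear-interpolation percentile, the
common numeric-stack default), objective fraction `f = 0.5`.

Two documented choices:

* **Threshold level.** The percentile is computed per sample over
  *reaction-level* mapped values, because the extraction consumes
  reaction-level data; `threshold_for_sample(..., level="gene")` computes
  it over raw gene values instead.
* **Canonicalization.** The GIMME LP typically has alternate optima, and
  the active set would then depend on solver internals.  A third solve
  pins the penalty sum at `I*` and minimizes total absolute flux, giving a
  deterministic representative flux.

The active set is `{x_j ≥ T} ∪ {unmapped} ∪ {|v_j| > tol}`; everything
else is removed together with orphaned metabolites and genes (orphan
pruning after reaction removal is itself a documented choice).  Pruning
may leave dead-end reactions; they are retained — no flux-consistency
trimming is applied by default.  Every context model still attains
`f·V_opt` of its parent's optimum.

Combinatory models: a binary vector marks reactions active in either
(union) or both (intersection) of two context models, and is fed back
through GIMME with threshold 0.5 — reactions marked 0 get penalty 0.5,
reactions marked 1 none, and mass balance can override the data where
pruning would break the objective floor.

## Differential flux inference

Gene-level differential input is a table of signed log2 fold changes with
q-values; genes with `q ≥ alpha` (default 0.01 — the boundary is
discarded) are dropped, and the significant fold changes are mapped onto
reactions with the same min/max rule, giving a signed direction set `D`.

The flux difference `Δv` between two steady states satisfies `S Δv = 0`
and `Δv_j ∈ [lb_j − ub_j, ub_j − lb_j]`.  Two steps:

1. **Consistency maximization (MILP).**  Binary `y_j` per `j ∈ D`;
   `y_j = 1` enforces `sign(w_j)·Δv_j ≥ ε` through big-M linking
   (`M` defaults to twice the largest bound range); maximize `N = Σ y_j`.
2. **Inconsistency minimization (QP).**  The optimal assignment `y*` is
   fixed — a deterministic, convex restriction of "`Σ y_j = N*`" that
   avoids an MIQP — and `Σ_{j∉D} Δv_j²` is minimized subject to the
   step-1 sign constraints.  The QP is solved in the null space of `S`
   (mass balance exact by construction; the toy networks conserve
   cofactor pairs, so `S` is rank-deficient and explicit equality
   constraints would be ill-conditioned), with SLSQP and a trust-region
   fallback.  An L1 variant (`objective="l1"`, pure LP) is available.

`ε` (default 0.1) plays two roles — the consistency margin and the
altered-set cutoff `|Δv_j| ≥ ε` — with a shared default but independent
config keys, since the two uses are conceptually distinct.  The terminal
output is the altered reaction set and the union of their GPR genes;
downstream enrichment is out of scope by design (external databases).

## Evaluation

Predicted and measured fluxes are compared on their common reactions
(at least 4 required) via Pearson's r and MSE (denominator `n`, stated
for bit-reproducibility).  Two correlations are compared with Fisher's z:

    z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3)),

two-sided normal p, significance at 0.05.  Sample clustering is
agglomerative on Euclidean distances between log2-transformed profiles;
average linkage by default (complete and Ward available), samples
pre-sorted by id so ties break deterministically.  Cluster cutting (k or
height) is always caller-chosen, never automatic.

## The synthetic study

`make_toy_network` builds a ~26-reaction central-carbon toy: glycolysis-,
TCA-, pentose-phosphate-, storage- and fermentation-like modules with GPR
rules (including `and` complexes and `or` isozyme pairs), a biomass
reaction demanding pyruvate, pentose, acetyl-CoA, NADPH and GAM-scale ATP,
and the fixed NGAM drain.  The non-oxidative pentose branch
(transketolase-like, 3 C5 → 2 C6 + C3) returns surplus pentose to
glycolysis so the biomass NADPH:pentose ratio is satisfiable at any flux.

Two design features carry the scientific weight:

* **Bypass decoys.**  The network plants one-step shortcuts that are
  stoichiometrically equivalent to the multi-step glycolysis and TCA
  routes and whose genes are inactive in every phase.  Parsimonious FBA
  prefers a shortcut whenever it survives in a model, so the generic
  model mis-routes flux by construction and a context-extraction method
  improves predictions exactly insofar as it prunes the decoys.  Without
  such routes the generic model would already predict the true fluxes and
  data integration could never help.
* **Phase design.**  The three backbone modules are active in every phase
  (so every ground-truth submodel grows); the quiescent phase adds the
  storage cycle, the proliferation phase adds fermentation under an
  O2-limited medium (uptake 1.0 vs 10.0 mmol/gDW/h), which forces real
  fermentative flux in its ground truth — a genuine planted flux shift
  for the differential analysis.  Ground-truth fluxes are the two-stage
  FBA solutions of each phase's active submodel.

Gene values: gene g in phase p is `2^(b_g ± log2(F)/2 + ε)`, where `b_g`
is a per-gene baseline (Normal(5, 0.5) on the log2 scale), `F = 8` the
activity fold between active and inactive modules, and
`ε ~ Normal(0, σ_channel)` per replicate (two replicates per phase,
averaged downstream on the raw scale).  Both channels share baselines and
activity — the planted biology — and differ only in noise:
`σ_atac = 0.15` (accessibility-like) vs `σ_rna = 0.45` (expression-like),
encoding the lower signal-to-noise of expression data as a testable
generator parameter, not a claim about real assays.  Fermentation genes
carry a +1 log2 baseline offset: fermentative enzymes are constitutively
among the most abundant yeast proteins, and without the offset a low
baseline draw can push an off-phase-but-essential fermentation gene below
the extraction threshold for reasons that have nothing to do with channel
noise.  Differential tables plant significance directly (q = 0.001 for
genes whose module activity differs between the phases, 0.5 otherwise);
measured fluxes add `Normal(0, 0.05·|v| + 0.01)` noise to the ground-truth
solution over the central-carbon reactions (the storage cycle carries no
steady-state net flux and the decoys are model constructs, so neither is
"measured").

All randomness flows through per-purpose child seeds of one study seed;
every output is bit-reproducible.

**What passing tests show — and what they don't.**  The generator plants
a clean two-cluster gene-activity structure with lognormal noise, whole
modules switching between phases, and decoy routes whose pruning is the
single channel through which data quality affects flux predictions.  Real
data differ in every one of these respects: activity is graded rather
than binary, fold changes are gene-specific, noise is heteroskedastic and
correlated, and model errors (wrong stoichiometry, missing reactions) can
dominate data errors.  The synthetic result — the low-noise channel and
the intersection models out-predicting the high-noise channel — therefore
demonstrates that the *pipeline* faithfully transmits a channel's
signal-to-noise advantage into flux-prediction accuracy; it is not
evidence about any particular real assay pair.

## Numerical choices

* Tolerances (module `config`): bound-feasibility 1e-9 for model checks,
  mass-balance assertion 1e-6 on every returned flux vector and Δv,
  zero-flux classification 1e-6.
* LP/MILP: HiGHS via scipy (`linprog`/`milp`); infeasibility and
  unboundedness are explicit exceptions.
* GIMME step 3 pins the penalty sum with a 1e-9 slack row.
* Percentiles: linear interpolation between closest ranks.
* Problem sizes: the study sweep uses 20 seeded worlds × 3 phases — large
  enough that the channel ordering is stable across the sweep, small
  enough that the whole chain (≈ 1,000 LP solves) runs in seconds.

## Known limitations

* GIMME, union/intersection combination and the two-step differential
  inference are the only extraction/differential methods implemented;
  iMAT/INIT/E-Flux/PROM/mCADRE and MOOMIN/REMI-style alternatives are
  out of scope.
* No flux-consistency trimming of context models (dead ends retained).
* Upstream data processing (normalization, peak calling, differential
  statistics) is an input contract: callers supply fold changes and
  q-values.
* The SBML reader handles Level 3 + FBC via cobra; SBML writing is not
  supported (the JSON dialect is the native format).
* Enrichment analysis of altered genes requires external databases and is
  deliberately not implemented; the gene list is the terminal output.
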