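"""Metabolic-model data structures and model I/O.

A :class:`MetabolicModel` is the standard constraint-based representation of
a metabolic network: a stoichiometric matrix ``S`` (metabolites x
reactions), flux bounds ``lb_j <= v_j <= ub_j`` per reaction, boolean GPR
rules linking reactions to genes, and a designated objective reaction
(typically biomass).  Reversible reactions are encoded by a negative lower
bound — the model file never splits them; any splitting is a solver-layer
detail.

Energetic parameters follow consensus yeast-model conventions: the
growth-associated maintenance (GAM, mmol ATP/gDW, default 55.3) appears as
ATP-hydrolysis stoichiometry inside the biomass reaction, and the
non-growth-associated maintenance (NGAM, mmol ATP/gDW/h, default 0.7) is a
dedicated reaction with fixed bounds ``lb = ub = ngam``.

Models round-trip through a small JSON dialect (see :func:`write_model` /
:func:`read_model`); an optional reader for SBML Level 3 + FBC is provided
through cobra.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np

from . import config
from .errors import ModelSchemaError
from .gpr import GprEmpty, GprExpression, parse_gpr

#: Default growth-associated maintenance, mmol ATP per g dry weight.
DEFAULT_GAM = 55.3
#: Default non-growth-associated maintenance, mmol ATP per gDW per hour.
DEFAULT_NGAM = 0.7


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self):
        if not self.id:
            raise ModelSchemaError("metabolite with empty id")


@dataclass(frozen=True)
class Reaction:
    """A stoichiometry-balanced conversion with flux bounds and a GPR rule.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed, positive = produced).  Bounds are in mmol/gDW/h.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: GprExpression = field(default_factory=GprEmpty)
    name: str = ""
    subsystem: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise ModelSchemaError("reaction with empty id")
        if self.lower_bound > self.upper_bound:
            raise ModelSchemaError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > upper_bound {self.upper_bound}"
            )
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))

    @property
    def is_exchange(self) -> bool:
        """True for pure source/sink reactions touching a single metabolite."""
        return len(self.stoichiometry) == 1

    @property
    def genes(self) -> frozenset[str]:
        return self.gpr.genes()


@dataclass
class MetabolicModel:
    """A genome-scale (here: toy-scale) metabolic network model."""

    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_reaction: str
    gam: float = DEFAULT_GAM
    ngam: float = DEFAULT_NGAM

    def __post_init__(self):
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelSchemaError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelSchemaError(f"duplicate reaction ids: {dup}")
        met_set = set(met_ids)
        for rxn in self.reactions:
            for met in rxn.stoichiometry:
                if met not in met_set:
                    raise ModelSchemaError(
                        f"reaction {rxn.id!r} references unknown metabolite {met!r}"
                    )
        if self.objective_reaction not in set(rxn_ids):
            raise ModelSchemaError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )

    # ---- indexed access -------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> list[str]:
        """Sorted union of all GPR leaf genes."""
        out: set[str] = set()
        for rxn in self.reactions:
            out |= rxn.genes
        return sorted(out)

    def reaction(self, reaction_id: str) -> Reaction:
        try:
            return next(r for r in self.reactions if r.id == reaction_id)
        except StopIteration:
            raise KeyError(f"no reaction {reaction_id!r} in model {self.id!r}") from None

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (m metabolites x n reactions) in model order."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                S[met_index[met], j] = coef
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    # ---- derived models -------------------------------------------------

    def subset(self, keep_reactions: Iterable[str], model_id: Optional[str] = None) -> "MetabolicModel":
        """Submodel restricted to ``keep_reactions``; orphaned metabolites dropped.

        The objective reaction is always retained.
        """
        keep = set(keep_reactions) | {self.objective_reaction}
        unknown = keep - set(self.reaction_ids)
        if unknown:
            raise KeyError(f"unknown reactions {sorted(unknown)} in model {self.id!r}")
        reactions = [r for r in self.reactions if r.id in keep]
        used_mets = {m for r in reactions for m in r.stoichiometry}
        metabolites = [m for m in self.metabolites if m.id in used_mets]
        return MetabolicModel(
            id=model_id or f"{self.id}_sub",
            metabolites=metabolites,
            reactions=reactions,
            objective_reaction=self.objective_reaction,
            gam=self.gam,
            ngam=self.ngam,
        )

    def with_bounds(self, bounds: Mapping[str, tuple[float, float]]) -> "MetabolicModel":
        """Copy of the model with per-reaction bounds overridden."""
        unknown = set(bounds) - set(self.reaction_ids)
        if unknown:
            raise KeyError(f"unknown reactions {sorted(unknown)} in model {self.id!r}")
        reactions = [
            replace(r, lower_bound=bounds[r.id][0], upper_bound=bounds[r.id][1])
            if r.id in bounds
            else r
            for r in self.reactions
        ]
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=reactions,
            objective_reaction=self.objective_reaction,
            gam=self.gam,
            ngam=self.ngam,
        )

    def counts(self) -> dict[str, int]:
        """Reaction/metabolite/gene counts (the model-content summary)."""
        return {
            "reactions": len(self.reactions),
            "metabolites": len(self.metabolites),
            "genes": len(self.genes),
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.id == other.id
            and self.metabolites == other.metabolites
            and self.reactions == other.reactions
            and self.objective_reaction == other.objective_reaction
            and math.isclose(self.gam, other.gam)
            and math.isclose(self.ngam, other.ngam)
        )


@dataclass
class FluxVector:
    """A steady-state flux distribution with its objective value.

    Any flux vector returned by a solver in this package satisfies
    ``max_i |sum_j S_ij v_j| <= MASS_BALANCE_TOL`` and respects the bounds
    within ``FEASIBILITY_TOL``; :meth:`check` asserts both.
    """

    fluxes: dict[str, float]
    objective_value: float
    total_flux: Optional[float] = None

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self.fluxes

    def as_array(self, reaction_ids: Iterable[str]) -> np.ndarray:
        return np.array([self.fluxes[r] for r in reaction_ids], dtype=float)

    def check(self, model: MetabolicModel) -> None:
        """Assert conservation and bound feasibility against ``model``."""
        v = self.as_array(model.reaction_ids)
        residual = np.abs(model.stoichiometric_matrix() @ v).max(initial=0.0)
        if residual > config.MASS_BALANCE_TOL:
            raise AssertionError(
                f"mass-balance residual {residual:.3e} exceeds {config.MASS_BALANCE_TOL:.0e}"
            )
        lb, ub = model.bounds_arrays()
        if np.any(v < lb - 1e-6) or np.any(v > ub + 1e-6):
            worst = float(np.maximum(lb - v, v - ub).max())
            raise AssertionError(f"bound violation of {worst:.3e}")


# ---- JSON dialect -------------------------------------------------------


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: float(v) for k, v in r.stoichiometry.items()},
                "lower_bound": float(r.lower_bound),
                "upper_bound": float(r.upper_bound),
                "gpr": r.gpr.render(),
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "genes": model.genes,
        "objective": model.objective_reaction,
        "gam": float(model.gam),
        "ngam": float(model.ngam),
    }


def model_from_dict(doc: Mapping) -> MetabolicModel:
    for key in ("id", "metabolites", "reactions", "objective"):
        if key not in doc:
            raise ModelSchemaError(f"model document missing required field {key!r}")
    metabolites = []
    for record in doc["metabolites"]:
        if "id" not in record:
            raise ModelSchemaError(f"metabolite record missing 'id': {record!r}")
        metabolites.append(
            Metabolite(
                id=record["id"],
                name=record.get("name", ""),
                compartment=record.get("compartment", "c"),
            )
        )
    reactions = []
    for record in doc["reactions"]:
        for key in ("id", "stoichiometry", "lower_bound", "upper_bound"):
            if key not in record:
                raise ModelSchemaError(
                    f"reaction record {record.get('id', '?')!r} missing required field {key!r}"
                )
        reactions.append(
            Reaction(
                id=record["id"],
                name=record.get("name", ""),
                stoichiometry=record["stoichiometry"],
                lower_bound=float(record["lower_bound"]),
                upper_bound=float(record["upper_bound"]),
                gpr=parse_gpr(record.get("gpr") or ""),
                subsystem=record.get("subsystem"),
            )
        )
    return MetabolicModel(
        id=doc["id"],
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction=doc["objective"],
        gam=float(doc.get("gam", DEFAULT_GAM)),
        ngam=float(doc.get("ngam", DEFAULT_NGAM)),
    )


def write_model(model: MetabolicModel, path: Union[str, Path]) -> None:
    """Serialize a model to the package's JSON dialect (UTF-8)."""
    Path(path).write_text(
        json.dumps(model_to_dict(model), indent=1, sort_keys=False) + "\n",
        encoding="utf-8",
    )


def read_model(path: Union[str, Path]) -> MetabolicModel:
    """Read a model from the JSON dialect; raises ModelSchemaError on bad documents."""
    with open(path, encoding="utf-8") as handle:
        try:
            doc = json.load(handle)
        except json.JSONDecodeError as exc:
            raise ModelSchemaError(f"not valid JSON: {exc}") from exc
    return model_from_dict(doc)


def read_sbml_model(path: Union[str, Path]) -> MetabolicModel:
    """Optional reader for SBML Level 3 + FBC documents (bounds + gene associations).

    Parsing is delegated to cobra/libsbml; the result is converted into this
    package's :class:`MetabolicModel`.  The SBML objective is taken as the
    (single) reaction with a nonzero objective coefficient.
    """
    import cobra  # deferred: SBML support is optional

    cmodel = cobra.io.read_sbml_model(str(path))
    metabolites = [
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "c")
        for m in cmodel.metabolites
    ]
    reactions = [
        Reaction(
            id=r.id,
            name=r.name or "",
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            gpr=parse_gpr(r.gene_reaction_rule or ""),
            subsystem=r.subsystem or None,
        )
        for r in cmodel.reactions
    ]
    objectives = [r.id for r in cmodel.reactions if r.objective_coefficient]
    if len(objectives) != 1:
        raise ModelSchemaError(
            f"expected exactly one objective reaction in SBML model, found {objectives}"
        )
    return MetabolicModel(
        id=cmodel.id or Path(path).stem,
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction=objectives[0],
    )
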