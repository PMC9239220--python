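"""Shared fixtures: small hand-built networks and a default synthetic study."""

from __future__ import annotations

import pytest

from ymcflux.gpr import parse_gpr
from ymcflux.model import MetabolicModel, Metabolite, Reaction
from ymcflux.synthetic import SyntheticSpec, ground_truth, make_toy_network


def build_chain(ex_ub: float = 10.0) -> MetabolicModel:
    """EX_A -> R1 -> GROW: one substrate, one conversion, one drain."""
    return MetabolicModel(
        id="chain",
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("EX_A", {"A": 1}, 0, ex_ub),
            Reaction("R1", {"A": -1, "B": 1}, 0, 1000, gpr=parse_gpr("g1")),
            Reaction("GROW", {"B": -1}, 0, 1000),
        ],
        objective_reaction="GROW",
    )


def build_two_route(r1_ub: float = 10.0) -> MetabolicModel:
    """Two parallel A->B conversions (isozyme-style routes) feeding the drain."""
    return MetabolicModel(
        id="two_route",
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("EX_A", {"A": 1}, 0, 10),
            Reaction("R1", {"A": -1, "B": 1}, 0, r1_ub, gpr=parse_gpr("g1")),
            Reaction("R2", {"A": -1, "B": 1}, 0, 10, gpr=parse_gpr("g2")),
            Reaction("GROW", {"B": -1}, 0, 1000),
        ],
        objective_reaction="GROW",
    )


def build_parallel_paths() -> MetabolicModel:
    """A short route (P1) and a long route (P2a+P2b) from substrate to drain."""
    return MetabolicModel(
        id="parallel",
        metabolites=[Metabolite("A"), Metabolite("B"), Metabolite("C")],
        reactions=[
            Reaction("EX_A", {"A": 1}, 0, 10),
            Reaction("P1", {"A": -1, "B": 1}, 0, 1000),
            Reaction("P2a", {"A": -1, "C": 1}, 0, 1000),
            Reaction("P2b", {"C": -1, "B": 1}, 0, 1000),
            Reaction("GROW", {"B": -1}, 0, 1000),
        ],
        objective_reaction="GROW",
    )


@pytest.fixture
def chain_model() -> MetabolicModel:
    return build_chain()


@pytest.fixture
def two_route_model() -> MetabolicModel:
    return build_two_route()


@pytest.fixture
def parallel_model() -> MetabolicModel:
    return build_parallel_paths()


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def toy_model(default_spec):
    return make_toy_network(default_spec)


@pytest.fixture(scope="session")
def toy_truth(default_spec, toy_model):
    return ground_truth(toy_model, default_spec)
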