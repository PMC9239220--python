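"""Differential flux inference: filtering, closed-form chains, recovery."""

import numpy as np
import pandas as pd
import pytest

from ymcflux.deltafba import (
    DeltaFbaConfig,
    DifferentialGeneTable,
    altered_pathway_genes,
    delta_fba,
    filter_significant,
    map_differential_to_reactions,
)
from ymcflux.gpr import parse_gpr
from ymcflux.model import MetabolicModel, Metabolite, Reaction
from ymcflux.omics import ReactionDataVector
from ymcflux.synthetic import (
    SyntheticSpec,
    ground_truth,
    make_toy_network,
    simulate_differential,
)


def _diff_table(rows):
    return DifferentialGeneTable(
        pd.DataFrame(rows, columns=["gene", "log2fc", "qvalue"]).set_index("gene")
    )


class TestFilterSignificant:
    def test_boundary_is_excluded(self):
        table = _diff_table(
            [("a", 1.0, 0.005), ("b", 1.0, 0.01), ("c", -2.0, 0.5), ("d", 0.5, 0.0099)]
        )
        kept = filter_significant(table, alpha=0.01)
        assert kept.genes == ["a", "d"]  # q = 0.01 itself is discarded

    def test_empty_in_empty_out(self):
        assert filter_significant(_diff_table([]), 0.01).genes == []

    def test_qvalue_validation(self):
        with pytest.raises(Exception, match="q-value"):
            _diff_table([("a", 1.0, 1.5)])


def _chain_with_gene():
    return MetabolicModel(
        id="chain",
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("EX_A", {"A": 1}, 0, 10),
            Reaction("R1", {"A": -1, "B": 1}, 0, 10, gpr=parse_gpr("g1")),
            Reaction("GROW", {"B": -1}, 0, 1000),
        ],
        objective_reaction="GROW",
    )


class TestChainClosedForm:
    @pytest.mark.parametrize("w, sign", [(1.0, 1.0), (-1.0, -1.0)])
    def test_delta_is_epsilon_along_the_whole_chain(self, w, sign):
        """Conservation forces equal Δv along a chain; the L2 step shrinks it to ε."""
        model = _chain_with_gene()
        data = ReactionDataVector(
            {"EX_A": None, "R1": w, "GROW": None}, channel="foldchange"
        )
        result = delta_fba(model, data, DeltaFbaConfig(epsilon=0.1))
        for rxn in model.reaction_ids:
            assert result.delta_v[rxn] == pytest.approx(sign * 0.1, abs=1e-6)
        assert result.n_consistent == 1
        assert result.altered_reactions == set(model.reaction_ids)
        assert result.altered_genes == {"g1"}

    def test_empty_direction_set_gives_zero(self):
        model = _chain_with_gene()
        data = ReactionDataVector({r: None for r in model.reaction_ids}, channel="foldchange")
        result = delta_fba(model, data)
        assert all(v == 0.0 for v in result.delta_v.values())
        assert result.altered_reactions == set()
        assert result.n_consistent == 0

    def test_l1_variant_matches_the_chain_closed_form(self):
        model = _chain_with_gene()
        data = ReactionDataVector(
            {"EX_A": None, "R1": 1.0, "GROW": None}, channel="foldchange"
        )
        result = delta_fba(model, data, DeltaFbaConfig(objective="l1"))
        for rxn in model.reaction_ids:
            assert result.delta_v[rxn] == pytest.approx(0.1, abs=1e-6)


class TestOnToyNetwork:
    def test_conservation_of_delta(self, toy_model, default_spec):
        diff = simulate_differential(toy_model, default_spec, "earlyRC", "lateRB")
        mapped = map_differential_to_reactions(toy_model, filter_significant(diff))
        result = delta_fba(toy_model, mapped)
        S = toy_model.stoichiometric_matrix()
        d = result.as_array(toy_model.reaction_ids)
        assert np.abs(S @ d).max() <= 1e-6

    def test_n_star_monotone_in_epsilon(self, toy_model, default_spec):
        diff = simulate_differential(toy_model, default_spec, "earlyRC", "lateRB")
        mapped = map_differential_to_reactions(toy_model, filter_significant(diff))
        n_values = [
            delta_fba(toy_model, mapped, DeltaFbaConfig(epsilon=e)).n_consistent
            for e in (0.05, 0.1, 1.0, 25.0)
        ]
        assert all(b <= a for a, b in zip(n_values, n_values[1:]))

    def test_planted_shift_signs_recovered(self):
        """Module switches planted between phases are recovered in sign on the
        reactions whose ground-truth flux actually shifts."""
        agree = total = 0
        for seed in range(1, 21):
            spec = SyntheticSpec(seed=seed)
            model = make_toy_network(spec)
            truth = ground_truth(model, spec)
            diff = simulate_differential(model, spec, "earlyRC", "lateRB")
            mapped = map_differential_to_reactions(model, filter_significant(diff))
            result = delta_fba(model, mapped)
            shift = {
                r: truth.true_flux["lateRB"].fluxes.get(r, 0.0)
                - truth.true_flux["earlyRC"].fluxes.get(r, 0.0)
                for r in model.reaction_ids
            }
            perturbed = [r for r in result.direction_set if abs(shift[r]) >= 0.2]
            total += len(perturbed)
            agree += sum(
                1
                for r in perturbed
                if np.sign(result.delta_v[r]) == np.sign(result.direction_set[r])
            )
        assert total > 0
        assert agree / total >= 0.95


def test_altered_genes_are_the_union_of_gpr_leaves():
    model = MetabolicModel(
        id="m",
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("EX_A", {"A": 1}, 0, 10),
            Reaction("R1", {"A": -1, "B": 1}, 0, 10, gpr=parse_gpr("g1 and g2")),
            Reaction("R2", {"A": -1, "B": 1}, 0, 10, gpr=parse_gpr("g2 or g3")),
            Reaction("GROW", {"B": -1}, 0, 1000),
        ],
        objective_reaction="GROW",
    )
    data = ReactionDataVector(
        {"EX_A": None, "R1": 1.0, "R2": 1.0, "GROW": None}, channel="foldchange"
    )
    result = delta_fba(model, data)
    genes = altered_pathway_genes(result, model)
    assert genes == sorted(set(genes))  # deterministic, deduplicated
    if {"R1", "R2"} <= result.altered_reactions:
        assert genes == ["g1", "g2", "g3"]  # shared gene listed once
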