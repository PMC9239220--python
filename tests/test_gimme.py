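"""GIMME extraction: worked examples, combinatory models, oracle equivalence."""

import numpy as np
import pytest

from tests._oracles import gimme_inconsistency_oracle
from tests.conftest import build_two_route
from ymcflux.errors import InfeasibleError
from ymcflux.fba import solve_fba
from ymcflux.gimme import GimmeConfig, combine_activity, contextualize_binary, gimme
from ymcflux.omics import ReactionDataVector
from ymcflux.synthetic import make_random_network


def _data(model, **values):
    full = {r: values.get(r) for r in model.reaction_ids}
    return ReactionDataVector(full, sample="s", channel="rna")


class TestWorkedExamples:
    def test_supported_route_carries_all_flux(self, two_route_model):
        data = _data(two_route_model, R1=10.0, R2=1.0)
        result = gimme(two_route_model, data, GimmeConfig(threshold=5.0))
        assert result.inconsistency_score == pytest.approx(0.0, abs=1e-9)
        assert result.active_reactions == {"EX_A", "R1", "GROW"}
        assert "R2" not in result.context_model.reaction_ids

    def test_objective_floor_forces_the_penalized_route(self):
        model = build_two_route(r1_ub=3.0)
        data = _data(model, R1=10.0, R2=1.0)
        result = gimme(model, data, GimmeConfig(threshold=5.0, objective_fraction=0.5))
        # floor is 5, R1 caps at 3: R2 must carry 2 at penalty 4 each
        assert result.inconsistency_score == pytest.approx(8.0, abs=1e-6)
        assert result.flux["R1"] == pytest.approx(3.0)
        assert result.flux["R2"] == pytest.approx(2.0)
        assert result.flux["GROW"] == pytest.approx(5.0)

    def test_all_values_above_threshold_keeps_everything(self, two_route_model):
        data = _data(two_route_model, R1=9.0, R2=8.0)
        result = gimme(two_route_model, data, GimmeConfig(threshold=5.0))
        assert result.inconsistency_score == pytest.approx(0.0, abs=1e-9)
        assert set(result.context_model.reaction_ids) == set(two_route_model.reaction_ids)

    def test_context_model_still_attains_the_floor(self, two_route_model):
        data = _data(two_route_model, R1=10.0, R2=1.0)
        result = gimme(two_route_model, data, GimmeConfig(threshold=5.0, objective_fraction=0.5))
        context_opt = solve_fba(result.context_model).objective_value
        assert context_opt >= 0.5 * result.v_opt - 1e-6


class TestCombine:
    def test_union_and_intersection(self, two_route_model):
        a, b = {"R1", "EX_A"}, {"R2", "EX_A"}
        union = combine_activity(a, b, "union", two_route_model)
        inter = combine_activity(a, b, "intersection", two_route_model)
        assert union.values == {"EX_A": 1.0, "R1": 1.0, "R2": 1.0, "GROW": 0.0}
        assert inter.values == {"EX_A": 1.0, "R1": 0.0, "R2": 0.0, "GROW": 0.0}
        assert union.channel == "binary"

    def test_identical_sets_make_union_equal_intersection(self, two_route_model):
        a = {"R1", "EX_A", "GROW"}
        union = combine_activity(a, a, "union", two_route_model)
        inter = combine_activity(a, a, "intersection", two_route_model)
        assert union.values == inter.values

    def test_unknown_reaction_rejected(self, two_route_model):
        with pytest.raises(KeyError, match="ghost"):
            combine_activity({"ghost"}, set(), "union", two_route_model)


class TestContextualizeBinary:
    def test_all_ones_keeps_the_full_model(self, two_route_model):
        binary = combine_activity(
            set(two_route_model.reaction_ids), set(), "union", two_route_model
        )
        result = contextualize_binary(two_route_model, binary)
        assert result.inconsistency_score == pytest.approx(0.0, abs=1e-9)
        assert set(result.context_model.reaction_ids) == set(two_route_model.reaction_ids)

    def test_zero_marked_redundant_route_is_pruned(self, two_route_model):
        active = {"EX_A", "R1", "GROW"}
        binary = combine_activity(active, active, "intersection", two_route_model)
        result = contextualize_binary(two_route_model, binary)
        assert "R2" not in result.context_model.reaction_ids
        assert "R1" in result.context_model.reaction_ids

    def test_mass_balance_overrides_all_zero_routes(self, two_route_model):
        # both routes marked 0: the objective floor still forces one through
        binary = combine_activity({"EX_A", "GROW"}, {"EX_A", "GROW"}, "union", two_route_model)
        result = contextualize_binary(two_route_model, binary)
        floor = 0.5 * result.v_opt
        assert result.flux["GROW"] >= floor - 1e-6
        assert result.flux["R1"] + result.flux["R2"] >= floor - 1e-6
        assert result.inconsistency_score == pytest.approx(0.5 * floor, abs=1e-6)
        kept = {"R1", "R2"} & set(result.context_model.reaction_ids)
        assert kept  # a minimal penalized path survives

    def test_non_binary_values_rejected(self, two_route_model):
        vector = ReactionDataVector(
            {r: 0.5 for r in two_route_model.reaction_ids}, channel="binary"
        )
        with pytest.raises(ValueError, match="non-binary"):
            contextualize_binary(two_route_model, vector)


def _random_penalized_instance(seed):
    model = make_random_network(seed, max_reactions=8)
    rng = np.random.default_rng([seed, 5])
    values = {
        r: (None if rng.random() < 0.2 else float(rng.uniform(0, 10)))
        for r in model.reaction_ids
    }
    data = ReactionDataVector(values, sample="s", channel="rna")
    return model, data


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(15))
    def test_inconsistency_matches_orthant_enumeration(self, seed):
        """I* equals a brute-force minimum over sign labelings of penalized fluxes."""
        model, data = _random_penalized_instance(seed)
        cfg = GimmeConfig(threshold=5.0, objective_fraction=0.5)
        result = gimme(model, data, cfg)
        expected = gimme_inconsistency_oracle(
            model, result.penalties, 0.5 * result.v_opt
        )
        assert result.inconsistency_score == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_monotone_in_threshold_and_fraction(self, seed):
        model, data = _random_penalized_instance(seed)
        scores_t = [
            gimme(model, data, GimmeConfig(threshold=t)).inconsistency_score
            for t in (2.0, 5.0, 8.0)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(scores_t, scores_t[1:]))
        scores_f = [
            gimme(model, data, GimmeConfig(threshold=5.0, objective_fraction=f)).inconsistency_score
            for f in (0.25, 0.5, 0.9)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(scores_f, scores_f[1:]))


def test_nonpositive_optimum_is_rejected():
    from tests.conftest import build_chain

    model = build_chain(ex_ub=0.0)
    data = ReactionDataVector({r: 1.0 for r in model.reaction_ids})
    with pytest.raises(InfeasibleError, match="V_opt"):
        gimme(model, data, GimmeConfig(threshold=5.0))
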