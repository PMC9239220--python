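"""Synthetic-study generator: determinism, feasibility, planted structure."""

import json

import numpy as np
import pytest

from ymcflux.fba import solve_fba
from ymcflux.model import model_to_dict
from ymcflux.pipeline import apply_medium
from ymcflux.synthetic import (
    MODULES,
    SyntheticSpec,
    gene_modules,
    ground_truth,
    make_toy_network,
    reaction_modules,
    simulate_differential,
    simulate_measured_fluxes,
    simulate_omics,
)


class TestNetwork:
    def test_feasible_with_positive_growth(self, toy_model, default_spec):
        for phase in default_spec.phases:
            constrained = apply_medium(toy_model, default_spec.simulation_config(phase))
            assert solve_fba(constrained).objective_value > 0

    def test_has_and_and_or_rules(self, toy_model):
        rendered = [r.gpr.render() for r in toy_model.reactions]
        assert any(" and " in t for t in rendered)
        assert any(" or " in t for t in rendered)

    def test_identical_seed_identical_json(self):
        a = model_to_dict(make_toy_network(SyntheticSpec(seed=4)))
        b = model_to_dict(make_toy_network(SyntheticSpec(seed=4)))
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_maintenance_reaction_is_fixed_and_unmapped(self, toy_model):
        atpm = toy_model.reaction("ATPM")
        assert atpm.lower_bound == atpm.upper_bound == toy_model.ngam
        assert atpm.gpr.is_empty  # never prunable by data

    def test_biomass_carries_the_gam_atp_cost(self, toy_model):
        biomass = toy_model.reaction("BIOMASS")
        assert biomass.stoichiometry["atp_c"] == pytest.approx(-toy_model.gam)
        assert biomass.stoichiometry["adp_c"] == pytest.approx(toy_model.gam)

    def test_each_phase_submodel_remains_feasible(self, toy_model, toy_truth, default_spec):
        """The backbone guarantees growth even with whole modules disabled."""
        for phase in default_spec.phases:
            sub = toy_model.subset(toy_truth.active_reactions[phase])
            constrained = apply_medium(sub, default_spec.simulation_config(phase))
            assert solve_fba(constrained).objective_value > 0

    def test_module_subset_selection(self):
        spec = SyntheticSpec(
            seed=0,
            n_pathway_modules=3,
            phase_design={"p": frozenset({"glycolysis", "tca", "ppp", "storage"})},
            o2_uptake={"p": 10.0},
        )
        model = make_toy_network(spec)
        modules = set(reaction_modules(model).values())
        assert "storage" not in modules and "fermentation" not in modules
        assert "bypass" in modules  # decoys are always present

    def test_backbone_cannot_be_disabled(self):
        with pytest.raises(ValueError, match="backbone"):
            SyntheticSpec(seed=0, phase_design={"p": frozenset({"glycolysis"})},
                          o2_uptake={"p": 10.0})


class TestOmics:
    def test_fixed_seed_reproduces_tables_exactly(self, toy_model, default_spec):
        rna1, atac1 = simulate_omics(toy_model, default_spec)
        rna2, atac2 = simulate_omics(toy_model, default_spec)
        assert rna1.data.equals(rna2.data)
        assert atac1.data.equals(atac2.data)

    def test_noise_free_channels_coincide(self, toy_model):
        spec = SyntheticSpec(seed=3, noise_sigma_atac=0.0, noise_sigma_rna=0.0)
        rna, atac = simulate_omics(toy_model, spec)
        assert np.allclose(rna.data.to_numpy(), atac.data.to_numpy())

    def test_active_modules_sit_above_inactive_ones_without_noise(self, toy_model):
        spec = SyntheticSpec(seed=3, noise_sigma_atac=0.0, noise_sigma_rna=0.0,
                             base_log2_sd=0.0, module_baseline_offset={})
        rna, _ = simulate_omics(toy_model, spec)
        modules = gene_modules(toy_model)
        for phase in spec.phases:
            sample = spec.phase_samples(phase)[0]
            values = rna.sample_values(sample)
            active = [values[g] for g in values if modules[g] in spec.phase_design[phase]]
            inactive = [values[g] for g in values if modules[g] not in spec.phase_design[phase]]
            assert min(active) > max(inactive)
            # the planted separation is exactly the activity fold
            assert min(active) / max(inactive) == pytest.approx(spec.activity_fold)


class TestDifferential:
    def test_same_phase_has_no_signal(self, toy_model, default_spec):
        diff = simulate_differential(toy_model, default_spec, "midOX", "midOX")
        assert np.allclose(diff.data["log2fc"], 0.0)
        assert (diff.data["qvalue"] == 0.5).all()

    def test_switched_off_module_is_planted_significant_and_down(self, toy_model, default_spec):
        diff = simulate_differential(toy_model, default_spec, "earlyRC", "midOX")
        modules = gene_modules(toy_model)
        for gene in diff.genes:
            if modules[gene] == "storage":  # on in earlyRC, off in midOX
                assert diff.data.loc[gene, "qvalue"] == 0.001
                assert diff.data.loc[gene, "log2fc"] < 0
            elif modules[gene] in ("glycolysis", "tca", "ppp", "bypass"):
                assert diff.data.loc[gene, "qvalue"] == 0.5

    def test_seed_determinism(self, toy_model, default_spec):
        a = simulate_differential(toy_model, default_spec, "earlyRC", "lateRB")
        b = simulate_differential(toy_model, default_spec, "earlyRC", "lateRB")
        assert a.data.equals(b.data)


class TestMeasuredFluxes:
    def test_noise_free_measurements_equal_the_truth(self, toy_model, toy_truth, default_spec):
        from dataclasses import replace

        spec = replace(default_spec, flux_noise_frac=0.0)
        measured = simulate_measured_fluxes(toy_model, toy_truth, "midOX", spec)
        for rxn, value in measured.fluxes.items():
            assert value == pytest.approx(toy_truth.true_flux["midOX"].fluxes.get(rxn, 0.0))

    def test_seed_determinism(self, toy_model, toy_truth, default_spec):
        a = simulate_measured_fluxes(toy_model, toy_truth, "midOX", default_spec)
        b = simulate_measured_fluxes(toy_model, toy_truth, "midOX", default_spec)
        assert a.fluxes == b.fluxes

    def test_truth_is_conserved_on_its_submodel(self, toy_model, toy_truth):
        sub = toy_model.subset(toy_truth.active_reactions["lateRB"])
        S = sub.stoichiometric_matrix()
        v = toy_truth.true_flux["lateRB"].as_array(sub.reaction_ids)
        assert np.abs(S @ v).max() <= 1e-6
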