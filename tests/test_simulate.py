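"""Generator contracts: determinism, calibration, layout, planted truth."""

import dataclasses
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from emtkit import (ConfigError, InputError, SimulationConfig,
                    simulate_bum_pvalues, simulate_combination,
                    simulate_drug_targets, simulate_expression,
                    simulate_pathways, simulate_ppi, simulate_screen_plate)
from emtkit.simulate import ba_edge_count


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"dilution_factor": 1.0},
        {"n_doses": 1},
        {"top_dose": 0.0},
        {"bum_a": 1.0},
        {"de_fraction": 1.2},
        {"planted_module_size": 500, "network_size": 100},
        {"enriched_pathways": (("NOPE", 2.0),)},
        {"combo_interaction": "mystery"},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)

    def test_dose_series_design(self):
        cfg = SimulationConfig()
        doses = cfg.doses
        assert len(doses) == 11 and doses[0] == 10.0
        assert np.allclose(doses[:-1] / doses[1:], 2.0)


class TestExpression:
    def test_pure_null_calibration(self):
        cfg = SimulationConfig(seed=5, n_genes=5000, de_fraction=0.0,
                               comparisons=("468_EGF",))
        sim = simulate_expression(cfg)
        p = sim.tables["468_EGF"].detected["p"].to_numpy()
        frac = (p < 0.05).mean()
        se = math.sqrt(0.05 * 0.95 / p.size)
        assert abs(frac - 0.05) < 3 * se
        assert sim.signal_genes["468_EGF"] == frozenset()

    def test_mixture_density_at_one(self):
        # f(1) = lam + (1-lam)*a = 0.6 + 0.4*0.3 = 0.72
        rng = np.random.default_rng(3)
        p = simulate_bum_pvalues(200_000, lam=0.6, a=0.3, rng=rng)
        width = 0.05
        density = (p >= 1.0 - width).mean() / width
        assert density == pytest.approx(0.72, abs=0.05)

    def test_same_seed_identical(self, small_config):
        a = simulate_expression(small_config)
        b = simulate_expression(small_config)
        for comparison in small_config.comparisons:
            pd.testing.assert_frame_equal(a.tables[comparison].data,
                                          b.tables[comparison].data)

    def test_enrichment_oversamples_pathway(self):
        cfg = SimulationConfig(seed=9, n_genes=4000,
                               enriched_pathways=(("PW001", 6.0),),
                               comparisons=("468_EGF",))
        sim = simulate_expression(cfg)
        signal = sim.signal_genes["468_EGF"]
        inside = sim.pathways["PW001"].genes
        frac_in = len(signal & inside) / len(inside)
        outside = set(cfg.gene_symbols()) - inside
        frac_out = len(signal & outside) / len(outside)
        assert frac_in > 2.0 * frac_out


class TestPPI:
    def test_edge_count_closed_form(self):
        cfg = SimulationConfig(seed=7, n_genes=600, comparisons=("468_EGF",),
                               network_size=50, attachment_parameter=2,
                               planted_module_size=5)
        sim = simulate_expression(cfg)
        ppi = simulate_ppi(cfg, sim)
        assert ppi.graph.number_of_edges() == ba_edge_count(50, 2) == 96

    def test_connected_and_simple(self, ppi_sim):
        graph = ppi_sim.graph
        assert nx.is_connected(graph)
        assert nx.number_of_selfloops(graph) == 0

    def test_module_planted_in_signal(self, small_config, expression_sim,
                                      ppi_sim):
        module = ppi_sim.planted_module
        assert len(module) == small_config.planted_module_size
        assert module <= set(ppi_sim.graph.nodes)
        signal = expression_sim.signal_genes[small_config.module_comparison]
        frac = len(module & signal) / len(module)
        assert frac >= small_config.module_signal_fraction - 0.15
        assert nx.is_connected(ppi_sim.graph.subgraph(module))

    def test_single_node_module_is_signal_gene(self):
        cfg = SimulationConfig(seed=2, n_genes=400, network_size=60,
                               planted_module_size=1,
                               comparisons=("468_EGF",))
        sim = simulate_expression(cfg)
        ppi = simulate_ppi(cfg, sim)
        (gene,) = ppi.planted_module
        assert gene in sim.signal_genes["468_EGF"]


class TestDrugTargets:
    def test_on_network_fractions(self, small_config, ppi_sim):
        cfg0 = dataclasses.replace(small_config, drug_on_network_fraction=0.0)
        none_on = simulate_drug_targets(cfg0, ppi_sim.graph)
        assert not set(none_on["target_gene"]) & set(ppi_sim.graph.nodes)
        cfg1 = dataclasses.replace(small_config, drug_on_network_fraction=1.0,
                                   n_drugs=10, max_targets_per_drug=1)
        all_on = simulate_drug_targets(cfg1, ppi_sim.graph)
        assert len(all_on) == 10
        assert set(all_on["target_gene"]) <= set(ppi_sim.graph.nodes)
        assert all_on["target_gene"].nunique() == 10

    def test_no_duplicate_pairs(self, small_config, ppi_sim):
        df = simulate_drug_targets(small_config, ppi_sim.graph)
        assert not df.duplicated(["drug_id", "target_gene"]).any()


class TestScreenPlate:
    def test_layout_partition(self, small_config):
        plate = simulate_screen_plate(small_config, "KIN-1", "EGF")
        counts = plate.wells["role"].value_counts()
        assert counts["pos_ctrl"] == 16 and counts["neg_ctrl"] == 16
        n_dose = small_config.n_doses * small_config.replicates_per_dose
        assert counts["dose"] == n_dose
        assert counts.sum() == 16 * 24
        doses = plate.wells.query("role == 'dose'")["dose_uM"]
        assert doses.nunique() == 11
        assert doses.max() == 10.0

    def test_neg_controls_at_stim_fraction(self, small_config):
        plate = simulate_screen_plate(small_config, "KIN-1", "EGF")
        labels = np.array(plate.truth["cell_vim_labels"])
        neg = plate.cells["role"].to_numpy() == "neg_ctrl"
        frac = labels[neg].mean()
        se = math.sqrt(0.6 * 0.4 / neg.sum())
        assert abs(frac - small_config.stim_vim_fraction) < 4 * se

    def test_dose_at_ic50_hits_midpoint(self):
        # plant the %vim+ IC50 on a dose actually present in the 1:2 series
        cfg = SimulationConfig(seed=13, mean_cells_per_well=200.0,
                               truth_ic50={"KIN-1": {"pct_vim_pos": 0.625,
                                                     "cell_count": 2.0}})
        plate = simulate_screen_plate(cfg, "KIN-1", "EGF")
        labels = np.array(plate.truth["cell_vim_labels"])
        at_mid = np.isclose(plate.cells["dose_uM"].to_numpy(),
                            cfg.truth_ic50["KIN-1"]["pct_vim_pos"])
        frac = labels[at_mid].mean()
        expected = 0.5 * (cfg.stim_vim_fraction
                          + cfg.baseline_vim_fraction["MDA-MB-468"])
        se = math.sqrt(expected * (1 - expected) / at_mid.sum())
        assert abs(frac - expected) < 4 * se

    def test_unknown_compound_rejected(self, small_config):
        with pytest.raises(InputError):
            simulate_screen_plate(small_config, "NOT-A-DRUG", "EGF")

    def test_determinism(self, small_config):
        a = simulate_screen_plate(small_config, "KIN-1", "EGF")
        b = simulate_screen_plate(small_config, "KIN-1", "EGF")
        pd.testing.assert_frame_equal(a.cells, b.cells)
        pd.testing.assert_frame_equal(a.wells, b.wells)


class TestCombination:
    def test_sham_self_combination(self):
        cfg = SimulationConfig(seed=1, combo_noise_sd=0.0,
                               combo_interaction="additive")
        sim = simulate_combination(cfg, "KIN-1", "KIN-1")
        m, dm = cfg.median_effect_truth["KIN-1"]
        for rec in sim.combination.itertuples(index=False):
            total = rec.dose_a_uM + rec.dose_b_uM
            fa_single = 1.0 / (1.0 + (dm / total) ** m)
            assert rec.fa == pytest.approx(fa_single, rel=1e-9)

    def test_missing_truth_rejected(self, small_config):
        with pytest.raises(InputError):
            simulate_combination(small_config, "KIN-1", "NOT-A-DRUG")

    def test_determinism(self, small_config):
        a = simulate_combination(small_config, "KIN-1", "KIN-2")
        b = simulate_combination(small_config, "KIN-1", "KIN-2")
        pd.testing.assert_frame_equal(a.combination, b.combination)
        pd.testing.assert_frame_equal(a.single_agent, b.single_agent)
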