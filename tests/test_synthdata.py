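"""The synthetic-data generator: layout, planting, link function, switches."""

from __future__ import annotations

import numpy as np
import pytest

from epibalance import SimConfig, simulate_experiment, write_simulation
from epibalance.arraydata import MARK_DNAME, MARK_H3K27ME3, MARK_H3K4ME3
from epibalance.synthdata import (
    apply_emt_switch,
    build_truth,
    generate_genome,
    sample_expression,
)


def tiny_cfg(**kwargs):
    defaults = dict(n_genes=30, seed=5)
    defaults.update(kwargs)
    return SimConfig(**defaults)


class TestGenome:
    def test_41_probes_per_window_at_200bp(self):
        cfg = tiny_cfg(n_genes=1, decoy_fraction=0.0)
        genome = generate_genome(cfg, np.random.default_rng(0))
        assert cfg.n_tile_probes == 41
        assert len(genome.probes) == 41

    def test_windows_never_overlap(self):
        cfg = tiny_cfg(n_genes=60)
        genome = generate_genome(cfg, np.random.default_rng(1))
        by_chrom = {}
        for g in genome.genes:
            by_chrom.setdefault(g.chrom, []).append(g.scoring_region)
        for regions in by_chrom.values():
            regions.sort()
            for (lo1, hi1), (lo2, hi2) in zip(regions, regions[1:]):
                assert hi1 <= lo2

    def test_decoys_unmapped(self):
        from epibalance import map_probes_to_genes

        cfg = tiny_cfg(n_genes=40)
        genome = generate_genome(cfg, np.random.default_rng(2))
        pgmap = map_probes_to_genes(genome.probes, genome.genes)
        assert genome.decoy_ids
        assert pgmap.n_unmapped == len(genome.decoy_ids)
        for pid in genome.decoy_ids:
            assert pid not in pgmap.assignments

    def test_infeasible_spacing_errors(self):
        with pytest.raises(ValueError, match="30 probes"):
            SimConfig(n_genes=5, probe_spacing_bp=1000)


class TestPlanting:
    def test_planted_totals_straddle_marked_threshold(self):
        cfg = tiny_cfg(n_genes=200, seed=9)
        sim = simulate_experiment(cfg)
        cond = cfg.conditions[0]
        for gt in sim.truth[cond].values():
            for mark in (MARK_H3K4ME3, MARK_H3K27ME3, MARK_DNAME):
                total = gt.planted_total(mark)
                if mark in gt.plans:
                    assert total >= 7 + 3  # marked with margin
                else:
                    assert total == 0.0

    def test_dname_probes_sporadic_histone_contiguous(self):
        cfg = tiny_cfg(n_genes=200, seed=9)
        sim = simulate_experiment(cfg)
        cond = cfg.conditions[0]
        for gt in sim.truth[cond].values():
            for mark, plan in gt.plans.items():
                if mark == MARK_DNAME:
                    assert len(plan.probe_indices) == cfg.dname_n_probes
                else:
                    idx = plan.probe_indices
                    assert list(idx) == list(range(idx[0], idx[0] + len(idx)))
                    assert cfg.island_len_min <= len(idx) <= cfg.island_len_max

    def test_seeds_differ_tracks_differ(self):
        a = simulate_experiment(tiny_cfg(seed=1))
        b = simulate_experiment(tiny_cfg(seed=2))
        cond = a.config.conditions[0]
        assert a.tracks[(MARK_H3K4ME3, cond)].values != b.tracks[(MARK_H3K4ME3, cond)].values


class TestExpressionLink:
    def test_degenerate_link_gives_constant_expression(self):
        cfg = tiny_cfg(beta_net=0.0, beta_dname_only=0.0, expr_noise_sigma=0.0)
        sim = simulate_experiment(cfg)
        for cond in cfg.conditions:
            assert all(v == 7.5 for v in sim.expression[cond].values.values())

    def test_mean_expression_tracks_planted_net(self):
        """A planted net of +10 shifts the pre-noise mean to 7.5 + 3.5."""
        cfg = tiny_cfg()
        truth = build_truth(cfg, {"G00000": "K4_only"}, np.random.default_rng(3))
        gt = truth["G00000"]
        assert gt.expr_mean_raw == pytest.approx(7.5 + 0.35 * gt.planted_net)

    def test_unmarked_gene_median_near_beta0(self):
        """Genes without marks sit at the baseline; the population median lies
        above it because activating marks outnumber repressive ones."""
        cfg = SimConfig(n_genes=5000, seed=21, switch_fraction=0.0)
        sim = simulate_experiment(cfg)
        cond = cfg.conditions[0]
        expr = sim.expression[cond].values
        none_vals = [expr[s] for s, gt in sim.truth[cond].items() if gt.cls == "none"]
        assert np.median(none_vals) == pytest.approx(cfg.beta0, abs=0.3)
        assert np.median(list(expr.values())) > cfg.beta0

    def test_dname_only_genes_below_population_median(self):
        cfg = SimConfig(n_genes=3000, seed=8)
        sim = simulate_experiment(cfg)
        cond = cfg.conditions[0]
        expr = sim.expression[cond].values
        dname_only = [expr[s] for s, gt in sim.truth[cond].items()
                      if gt.cls == "DNAMe_only"]
        assert np.median(dname_only) < np.median(list(expr.values()))


class TestSwitch:
    def test_zero_switch_fraction_noise_only_deltas(self):
        from epibalance import analyse_simulation

        cfg = SimConfig(n_genes=500, seed=17, switch_fraction=0.0)
        sim = simulate_experiment(cfg)
        assert sim.switched == set()
        _, _, contrast = analyse_simulation(sim)
        n_calls = sum(
            d.call != "unchanged"
            for deltas in contrast.mark_deltas.values()
            for d in deltas
        )
        # noise-only deltas essentially never exceed the |delta| > 5 rule
        assert n_calls / (3 * cfg.n_genes) <= 0.01

    def test_full_switch_redraws_every_gene(self):
        cfg = tiny_cfg(switch_fraction=1.0)
        truth1 = build_truth(
            cfg, {f"G{i:05d}": "none" for i in range(30)}, np.random.default_rng(1)
        )
        truth2, switched = apply_emt_switch(cfg, truth1, np.random.default_rng(2))
        assert switched == set(truth1)

    def test_gain_of_k4_island_plants_concordant_quadrant(self):
        cfg = tiny_cfg()
        truth1 = build_truth(cfg, {"A": "none"}, np.random.default_rng(1))
        truth2 = build_truth(cfg, {"A": "K4_only"}, np.random.default_rng(2))
        from epibalance.synthdata import planted_quadrants

        quads = planted_quadrants(cfg, truth1, truth2)
        assert quads["A"][MARK_H3K4ME3] == "K4up_exprUp"

    def test_switch_kernel_favors_k4_gain_and_dname_loss(self):
        cfg = SimConfig(n_genes=4000, seed=30, switch_fraction=0.3)
        sim = simulate_experiment(cfg)
        c1, c2 = cfg.conditions

        def mass(cond, mark):
            return sum(mark in gt.plans for gt in sim.truth[cond].values())

        assert mass(c2, MARK_H3K4ME3) > mass(c1, MARK_H3K4ME3)
        assert mass(c2, MARK_DNAME) < mass(c1, MARK_DNAME)


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = tiny_cfg(n_genes=50, seed=33)
        paths_a = write_simulation(simulate_experiment(cfg), tmp_path / "a")
        paths_b = write_simulation(simulate_experiment(cfg), tmp_path / "b")
        assert set(paths_a) == set(paths_b)
        for key in paths_a:
            assert paths_a[key].read_bytes() == paths_b[key].read_bytes(), key
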