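"""Gene-level totals, marked sets, mark classes and net intensity."""

from __future__ import annotations

import numpy as np
import pytest

from epibalance import (
    GeneMarkScore,
    MarkTrack,
    NetIntensity,
    aggregate_net_sums,
    classify_marks,
    map_probes_to_genes,
    marked_genes,
    net_intensity,
    total_gene_intensity,
)
from epibalance.genescore import (
    CLASS_NAMES,
    bivalent_k4_dname_genes,
    bivalent_k4_k27_genes,
    dname_without_k4_genes,
    genes_in_classes,
)
from epibalance.arraydata import ProbeGeneMap
from _oracles import brute_force_totals
from conftest import random_instance, random_track


def one_gene_map(probe_values):
    """A trivial map assigning every probe to gene A, plus a one-probe track."""
    track = MarkTrack("H3K4me3", "c1", dict(probe_values))
    pgmap = ProbeGeneMap(
        assignments={pid: frozenset({"A"}) for pid in probe_values}, n_unmapped=0
    )
    return track, pgmap


class TestTotalIntensity:
    def test_negative_values_count_as_zero(self):
        track, pgmap = one_gene_map({"p1": 2.0, "p2": -1.0, "p3": 3.5})
        (score,) = total_gene_intensity(track, pgmap, {"A"})
        assert score.total_intensity == pytest.approx(5.5)
        assert not score.marked

    def test_total_above_threshold_marks_gene(self):
        track, pgmap = one_gene_map({"p1": 4.0, "p2": 3.5})
        (score,) = total_gene_intensity(track, pgmap, {"A"})
        assert score.total_intensity == pytest.approx(7.5)
        assert score.marked

    def test_gene_without_probes_scores_zero(self):
        track, pgmap = one_gene_map({"p1": 4.0})
        scores = {s.symbol: s for s in total_gene_intensity(track, pgmap, {"A", "B"})}
        assert scores["B"].total_intensity == 0.0
        assert not scores["B"].marked

    def test_adding_negative_probe_never_changes_totals(self):
        track, pgmap = one_gene_map({"p1": 4.0, "p2": 1.5})
        (before,) = total_gene_intensity(track, pgmap, {"A"})
        track.values["p3"] = -2.5
        pgmap.assignments["p3"] = frozenset({"A"})
        (after,) = total_gene_intensity(track, pgmap, {"A"})
        assert after.total_intensity == before.total_intensity

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(23)
        genes, probes = random_instance(rng, n_genes=200, n_probes=3000)
        track = random_track(rng, probes)
        pgmap = map_probes_to_genes(probes, genes)
        universe = {g.symbol for g in genes}
        expected = brute_force_totals(track, pgmap.assignments, universe)
        for s in total_gene_intensity(track, pgmap, universe):
            total, n_sig, marked = expected[s.symbol]
            assert s.total_intensity == pytest.approx(total)
            assert s.n_significant_probes == n_sig
            assert s.marked == marked

    def test_probe_mask_restricts_scoring(self):
        track, pgmap = one_gene_map({"p1": 4.0, "p2": 5.0})
        (score,) = total_gene_intensity(track, pgmap, {"A"}, probe_mask={"p1"})
        assert score.total_intensity == pytest.approx(4.0)


class TestMarkedGenes:
    def test_strict_inequality_at_threshold(self):
        scores = [
            GeneMarkScore("A", "H3K4me3", "c1", 7.0, 3, 7.0 > 7),
            GeneMarkScore("B", "H3K4me3", "c1", 7.01, 3, 7.01 > 7),
        ]
        assert marked_genes(scores) == {"B"}

    def test_all_zero_totals(self):
        scores = [GeneMarkScore("A", "H3K4me3", "c1", 0.0, 0, False)]
        assert marked_genes(scores) == set()

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        genes, probes = random_instance(rng, n_genes=60, n_probes=1500)
        track = random_track(rng, probes)
        pgmap = map_probes_to_genes(probes, genes)
        universe = {g.symbol for g in genes}
        low = marked_genes(total_gene_intensity(track, pgmap, universe, threshold=4))
        high = marked_genes(total_gene_intensity(track, pgmap, universe, threshold=9))
        assert high <= low


class TestClassification:
    def test_unique_combination_classes(self):
        universe = {"A", "B", "C", "D"}
        classes = classify_marks({"A", "C"}, {"C"}, {"A"}, universe)
        by = {c.symbol: c.cls for c in classes}
        assert by == {"A": "K4_DNAMe", "B": "none", "C": "K4_K27", "D": "none"}

    def test_partition_sums_to_universe(self):
        rng = np.random.default_rng(8)
        universe = {f"G{i}" for i in range(300)}
        pick = lambda: {g for g in universe if rng.random() < 0.4}
        classes = classify_marks(pick(), pick(), pick(), universe)
        sizes = {cls: len(genes_in_classes(classes, cls)) for cls in CLASS_NAMES}
        assert sum(sizes.values()) == len(universe)

    def test_set_outside_universe_errors(self):
        with pytest.raises(ValueError, match="outside the universe"):
            classify_marks({"Z"}, set(), set(), {"A"})

    def test_group_accessors(self):
        universe = set("ABCDEFGH")
        classes = classify_marks(
            k4={"A", "E", "F", "H"},
            k27={"B", "E", "G", "H"},
            dname={"C", "F", "G", "H"},
            universe=universe,
        )
        assert bivalent_k4_k27_genes(classes) == {"E", "H"}
        assert bivalent_k4_dname_genes(classes) == {"F", "H"}
        assert dname_without_k4_genes(classes) == {"C", "G"}


class TestNetIntensity:
    def k4(self, **totals):
        return [GeneMarkScore(s, "H3K4me3", "c1", t, 0, t > 7) for s, t in totals.items()]

    def rep(self, **totals):
        return [GeneMarkScore(s, "H3K27me3", "c1", t, 0, t > 7) for s, t in totals.items()]

    def test_net_is_positive_minus_repressive(self):
        (net,) = net_intensity(self.k4(A=10.0), self.rep(A=4.0), "K4_vs_K27", {"A"})
        assert net.positive == 10.0
        assert net.negative == -4.0
        assert net.net == pytest.approx(6.0)

    def test_balanced_marks_give_zero_net(self):
        (net,) = net_intensity(self.k4(A=8.0), self.rep(A=8.0), "K4_vs_K27", {"A"})
        assert net.net == pytest.approx(0.0)

    def test_missing_score_errors(self):
        with pytest.raises(ValueError, match="missing a score"):
            net_intensity(self.k4(A=8.0), self.rep(B=3.0), "K4_vs_K27", {"A"})

    def test_aggregate_sums(self):
        nets = [
            NetIntensity("A", "c1", "K4_vs_K27", 3.0, -1.0),
            NetIntensity("B", "c1", "K4_vs_K27", 4.0, -2.0),
        ]
        assert aggregate_net_sums(nets) == (pytest.approx(7.0), pytest.approx(-3.0))

    def test_aggregate_empty_and_singleton(self):
        assert aggregate_net_sums([]) == (0, 0)
        one = NetIntensity("A", "c1", "K4_vs_DNAMe", 5.0, -2.5)
        assert aggregate_net_sums([one]) == (pytest.approx(5.0), pytest.approx(-2.5))
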