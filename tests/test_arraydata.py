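"""Readers, writers, window arithmetic, probe mapping and the gene universe."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epibalance import (
    ExpressionTable,
    GeneModel,
    ParseError,
    ProbeRecord,
    intersect_gene_universe,
    map_probes_to_genes,
    read_expression,
    read_gene_annotation,
    read_probe_coords,
    read_probe_track,
    write_expression,
    write_gene_annotation,
    write_probe_coords,
    write_track_values,
)
from _oracles import brute_force_probe_gene_map
from conftest import random_instance


class TestProbeTrackIO:
    def test_three_probe_identity(self, tmp_path):
        coords = tmp_path / "c.bed"
        coords.write_text("chr1\t100\t160\ta\nchr1\t300\t360\tb\nchr1\t500\t560\tc\n")
        vals = tmp_path / "v.tsv"
        vals.write_text("probe_id\tlog2ratio\na\t1.5\nb\t-0.2\nc\t0.0\n")
        track = read_probe_track(coords, vals, "H3K4me3", "c1")
        assert track.values == {"a": 1.5, "b": -0.2, "c": 0.0}
        assert track.missing == frozenset()

    def test_duplicate_probe_id_names_probe(self, tmp_path):
        coords = tmp_path / "c.bed"
        coords.write_text("chr1\t100\t160\tdup\nchr1\t300\t360\tdup\n")
        with pytest.raises(ParseError, match="dup"):
            read_probe_coords(coords)

    def test_missing_values_recorded_not_zeroed(self, tmp_path):
        coords = tmp_path / "c.bed"
        coords.write_text("chr1\t100\t160\ta\nchr1\t300\t360\tb\n")
        vals = tmp_path / "v.tsv"
        vals.write_text("probe_id\tlog2ratio\na\t0.7\n")
        track = read_probe_track(coords, vals, "DNAMe", "c1")
        assert track.missing == frozenset({"b"})
        assert "b" not in track.values

    @pytest.mark.parametrize(
        "bad_line, message",
        [
            ("a\tnot_a_number", "non-numeric"),
            ("a\tnan", "non-finite"),
            ("a", "expected 2 columns"),
        ],
    )
    def test_malformed_value_lines_report_line_number(self, tmp_path, bad_line, message):
        vals = tmp_path / "v.tsv"
        vals.write_text(f"probe_id\tlog2ratio\n{bad_line}\n")
        with pytest.raises(ParseError, match=message) as err:
            from epibalance.arraydata import read_track_values

            read_track_values(vals)
        assert ":2:" in str(err.value)

    def test_synthetic_track_round_trip(self, tmp_path, small_sim):
        """A generator-written track reads back with exactly the written values."""
        cond = small_sim.config.conditions[0]
        track = small_sim.tracks[("H3K27me3", cond)]
        write_probe_coords(small_sim.genome.probes, tmp_path / "c.bed")
        write_track_values(track.values, tmp_path / "v.tsv")
        back = read_probe_track(tmp_path / "c.bed", tmp_path / "v.tsv", "H3K27me3", cond)
        assert set(back.values) == set(track.values)
        for pid, v in track.values.items():
            assert back.values[pid] == float(f"{v:.6f}")


class TestGeneAnnotation:
    def test_plus_strand_window(self):
        gene = GeneModel("A", "chr1", "+", tss=100_000, gene_end=105_000)
        assert gene.window == (94_500, 102_500)
        assert gene.window[1] - gene.window[0] == 8_000

    def test_minus_strand_window_mirrored(self):
        gene = GeneModel("A", "chr1", "-", tss=100_000, gene_end=95_000)
        assert gene.window == (97_500, 105_500)

    def test_scoring_region_extends_past_window_for_long_genes(self):
        gene = GeneModel("A", "chr1", "+", tss=100_000, gene_end=120_000)
        assert gene.scoring_region == (94_500, 120_000)

    def test_round_trip_through_bed6(self, tmp_path):
        genes = [
            GeneModel("A", "chr1", "+", 100_000, 104_000),
            GeneModel("B", "chr2", "-", 50_000, 46_000),
        ]
        write_gene_annotation(genes, tmp_path / "g.bed")
        assert read_gene_annotation(tmp_path / "g.bed") == genes

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("")
        assert read_gene_annotation(path) == []

    @pytest.mark.parametrize(
        "line, message",
        [
            ("chr1\t100\t200\tA\t0\t?", "unknown strand"),
            ("chr1\t200\t100\tA\t0\t+", "txStart >= txEnd"),
        ],
    )
    def test_malformed_annotation(self, tmp_path, line, message):
        path = tmp_path / "g.bed"
        path.write_text(line + "\n")
        with pytest.raises(ParseError, match=message):
            read_gene_annotation(path)


class TestExpression:
    @pytest.mark.parametrize("raw, stored", [(3.2, 5.0), (17.9, 16.0), (8.0, 8.0)])
    def test_clipping(self, tmp_path, raw, stored):
        path = tmp_path / "e.tsv"
        path.write_text(f"symbol\tlog2_expression\nA\t{raw}\n")
        assert read_expression(path, "c1").values == {"A": stored}

    def test_duplicate_symbol_keeps_maximum(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("symbol\tlog2_expression\nA\t6.0\nA\t9.0\n")
        assert read_expression(path, "c1").values == {"A": 9.0}

    def test_clipping_idempotent_round_trip(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("symbol\tlog2_expression\nA\t2.0\nB\t20.0\nC\t7.25\n")
        once = read_expression(path, "c1")
        write_expression(once, tmp_path / "e2.tsv")
        twice = read_expression(tmp_path / "e2.tsv", "c1")
        assert once.values == twice.values

    def test_non_numeric_value_errors(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("symbol\tlog2_expression\nA\thigh\n")
        with pytest.raises(ParseError, match="non-numeric"):
            read_expression(path, "c1")


class TestProbeGeneMapping:
    def test_probe_inside_one_window(self):
        genes = [GeneModel("A", "chr1", "+", 100_000, 104_000)]
        probes = [ProbeRecord("p1", "chr1", 99_000, 99_060)]
        m = map_probes_to_genes(probes, genes)
        assert m.assignments == {"p1": frozenset({"A"})}
        assert m.n_unmapped == 0

    def test_probe_spanning_two_windows_maps_to_both(self):
        genes = [
            GeneModel("A", "chr1", "+", 100_000, 102_000),
            GeneModel("B", "chr1", "-", 97_000, 94_000),
        ]
        # A's window starts at 94500; B's window is [94500, 102500): overlap.
        probes = [ProbeRecord("p1", "chr1", 95_000, 95_060)]
        m = map_probes_to_genes(probes, genes)
        assert m.assignments["p1"] == frozenset({"A", "B"})

    def test_half_open_no_touching_overlap(self):
        genes = [GeneModel("A", "chr1", "+", 100_000, 104_000)]
        probes = [ProbeRecord("p1", "chr1", 104_000, 104_060)]
        # scoring region ends at max(102500, 104000) = 104000, half-open.
        m = map_probes_to_genes(probes, genes)
        assert m.n_unmapped == 1

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        genes, probes = random_instance(rng, n_genes=50, n_probes=1000)
        m = map_probes_to_genes(probes, genes)
        assert m.assignments == brute_force_probe_gene_map(probes, genes)

    @given(perm_seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_order_invariance(self, perm_seed):
        rng = np.random.default_rng(17)
        genes, probes = random_instance(rng, n_genes=20, n_probes=200)
        base = map_probes_to_genes(probes, genes)
        perm = np.random.default_rng(perm_seed)
        shuffled_probes = list(probes)
        shuffled_genes = list(genes)
        perm.shuffle(shuffled_probes)
        perm.shuffle(shuffled_genes)
        again = map_probes_to_genes(shuffled_probes, shuffled_genes)
        assert again.assignments == base.assignments
        assert again.n_unmapped == base.n_unmapped


class TestGeneUniverse:
    def test_intersection(self):
        expr = ExpressionTable("c1", {"A": 6.0, "B": 7.0, "C": 8.0})
        genes = [
            GeneModel("B", "chr1", "+", 1000, 2000),
            GeneModel("C", "chr1", "+", 50_000, 52_000),
            GeneModel("D", "chr1", "+", 90_000, 92_000),
        ]
        assert intersect_gene_universe(expr, genes) == {"B", "C"}

    def test_disjoint_inputs_error(self):
        expr = ExpressionTable("c1", {"A": 6.0})
        genes = [GeneModel("Z", "chr1", "+", 1000, 2000)]
        with pytest.raises(ValueError, match="empty gene universe"):
            intersect_gene_universe(expr, genes)
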