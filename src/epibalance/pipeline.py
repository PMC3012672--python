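"""End-to-end orchestration: score conditions, contrast them, score recovery.

These helpers chain the library stages the way the analysis scripts and the
acceptance checks run them: map probes to genes, score each condition's three
marks, classify genes, compute net intensities and activity associations,
contrast the two conditions, and — on synthetic data — compare everything to
the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .arraydata import (
    read_expression,
    read_gene_annotation,
    read_probe_coords,
    read_probe_track,
)
from .arraydata import (
    MARK_DNAME,
    MARK_H3K27ME3,
    MARK_H3K4ME3,
    MARKS,
    ExpressionTable,
    MarkTrack,
    ProbeGeneMap,
    intersect_gene_universe,
    map_probes_to_genes,
)
from .assoc_stats import (
    ActivityCall,
    NetQuadrantFractions,
    chi_square_2x2,
    classify_expression,
    net_quadrant_fractions,
)
from .bivalency import (
    BivalentGeneSummary,
    BivalentProbe,
    bivalent_probes,
    clustered_bivalent_genes,
)
from .differential import (
    ConcordanceQuadrant,
    DeltaRecord,
    concordance_quadrants,
    delta_expression,
    delta_mark,
)
from .genescore import (
    GeneMarkScore,
    MarkClass,
    NetIntensity,
    PAIR_K4_VS_DNAME,
    PAIR_K4_VS_K27,
    bivalent_k4_dname_genes,
    bivalent_k4_k27_genes,
    classify_marks,
    marked_genes,
    net_intensity,
    total_gene_intensity,
)
from .synthdata import Simulation


@dataclass
class ExperimentInputs:
    """File-backed inputs of one two-condition experiment."""

    conditions: tuple[str, str]
    probes: list
    genes: list
    tracks: dict[tuple[str, str], MarkTrack]  # (mark, condition)
    expression: dict[str, ExpressionTable]


def load_experiment(directory: str | Path) -> ExperimentInputs:
    """Read a simulation directory back through the standard file readers."""
    directory = Path(directory)
    with open(directory / "config.yaml", "r", encoding="utf-8") as handle:
        cond1, cond2 = yaml.safe_load(handle)["conditions"]
    probes = read_probe_coords(directory / "probes.bed")
    genes = read_gene_annotation(directory / "genes.bed")
    tracks = {}
    for mark in MARKS:
        for cond in (cond1, cond2):
            tracks[(mark, cond)] = read_probe_track(
                directory / "probes.bed", directory / f"{mark}_{cond}.tsv", mark, cond
            )
    expression = {
        cond: read_expression(directory / f"expression_{cond}.tsv", cond)
        for cond in (cond1, cond2)
    }
    return ExperimentInputs(
        conditions=(cond1, cond2),
        probes=probes,
        genes=genes,
        tracks=tracks,
        expression=expression,
    )


@dataclass
class ConditionAnalysis:
    """All gene-level results for one condition."""

    condition: str
    scores: dict[str, list[GeneMarkScore]]  # mark -> scores
    marked: dict[str, set[str]]  # mark -> marked genes
    classes: list[MarkClass]
    activity: list[ActivityCall]
    nets: dict[str, list[NetIntensity]]  # pair -> nets over the bivalent group
    net_fractions: dict[str, NetQuadrantFractions]
    bivalent: dict[str, tuple[list[BivalentProbe], list[BivalentGeneSummary]]]

    def class_by_symbol(self) -> dict[str, str]:
        return {c.symbol: c.cls for c in self.classes}


@dataclass
class EmtContrast:
    """Differential results between two conditions."""

    cond1: str
    cond2: str
    mark_deltas: dict[str, list[DeltaRecord]]
    expr_deltas: list[DeltaRecord]
    quadrants: dict[str, list[ConcordanceQuadrant]]  # mark -> quadrant calls


def analyse_condition(
    tracks: dict[str, MarkTrack],
    expr: ExpressionTable,
    probe_gene_map: ProbeGeneMap,
    universe: set[str],
    condition: str,
) -> ConditionAnalysis:
    """Score one condition's three tracks against one expression table."""
    scores = {
        mark: total_gene_intensity(tracks[mark], probe_gene_map, universe)
        for mark in MARKS
    }
    marked = {mark: marked_genes(scores[mark]) for mark in MARKS}
    classes = classify_marks(
        marked[MARK_H3K4ME3],
        marked[MARK_H3K27ME3],
        marked[MARK_DNAME],
        universe,
        condition=condition,
    )
    activity = classify_expression(expr)
    nets = {
        PAIR_K4_VS_K27: net_intensity(
            scores[MARK_H3K4ME3],
            scores[MARK_H3K27ME3],
            PAIR_K4_VS_K27,
            bivalent_k4_k27_genes(classes),
        ),
        PAIR_K4_VS_DNAME: net_intensity(
            scores[MARK_H3K4ME3],
            scores[MARK_DNAME],
            PAIR_K4_VS_DNAME,
            bivalent_k4_dname_genes(classes),
        ),
    }
    net_fractions = {
        pair: net_quadrant_fractions(pair_nets, activity)
        for pair, pair_nets in nets.items()
        if pair_nets
    }
    bivalent: dict[str, tuple[list[BivalentProbe], list[BivalentGeneSummary]]] = {}
    for a, b in ((MARK_H3K4ME3, MARK_H3K27ME3), (MARK_H3K4ME3, MARK_DNAME),
                 (MARK_H3K27ME3, MARK_DNAME)):
        probes = bivalent_probes(tracks[a], tracks[b])
        if probes:
            pair = probes[0].pair
        else:
            pair = {"H3K27me3": "K4_K27", "DNAMe": "K4_DNAMe"}.get(b, "K27_DNAMe")
            if (a, b) == (MARK_H3K27ME3, MARK_DNAME):
                pair = "K27_DNAMe"
        bivalent[pair] = (probes, clustered_bivalent_genes(probes, probe_gene_map))
    return ConditionAnalysis(
        condition=condition,
        scores=scores,
        marked=marked,
        classes=classes,
        activity=activity,
        nets=nets,
        net_fractions=net_fractions,
        bivalent=bivalent,
    )


def contrast_conditions(
    analysis1: ConditionAnalysis,
    analysis2: ConditionAnalysis,
    expr1: ExpressionTable,
    expr2: ExpressionTable,
) -> EmtContrast:
    """Deltas, differential calls and concordance quadrants between conditions."""
    mark_deltas = {
        mark: delta_mark(analysis1.scores[mark], analysis2.scores[mark])
        for mark in MARKS
    }
    expr_deltas = delta_expression(expr1, expr2)
    quadrants = {
        mark: concordance_quadrants(mark_deltas[mark], expr_deltas)
        for mark in (MARK_H3K4ME3, MARK_H3K27ME3)
    }
    return EmtContrast(
        cond1=analysis1.condition,
        cond2=analysis2.condition,
        mark_deltas=mark_deltas,
        expr_deltas=expr_deltas,
        quadrants=quadrants,
    )


def analyse_simulation(
    sim: Simulation,
) -> tuple[ConditionAnalysis, ConditionAnalysis, EmtContrast]:
    """Run the full gene-level pipeline on a simulation's emitted data."""
    pgmap = map_probes_to_genes(sim.genome.probes, sim.genome.genes)
    cond1, cond2 = sim.config.conditions
    universe = intersect_gene_universe(sim.expression[cond1], sim.genome.genes)
    a1 = analyse_condition(
        {mark: sim.tracks[(mark, cond1)] for mark in MARKS},
        sim.expression[cond1],
        pgmap,
        universe,
        cond1,
    )
    a2 = analyse_condition(
        {mark: sim.tracks[(mark, cond2)] for mark in MARKS},
        sim.expression[cond2],
        pgmap,
        universe,
        cond2,
    )
    contrast = contrast_conditions(a1, a2, sim.expression[cond1], sim.expression[cond2])
    return a1, a2, contrast


def evaluate_recovery(
    sim: Simulation,
    analysis1: ConditionAnalysis,
    analysis2: ConditionAnalysis,
    contrast: EmtContrast,
) -> dict[str, float]:
    """Score the pipeline's output against the simulation's planted truth.

    Returns class-recovery accuracy (pooled over both conditions), planted
    concordance-quadrant sensitivity, the chi-square of H3K4me3 marking vs
    activity in condition 1, and the net-intensity conditional fractions of
    the bivalent H3K4/K27 group in condition 1.
    """
    cond1, cond2 = sim.config.conditions
    n_total = 0
    n_correct = 0
    for analysis, cond in ((analysis1, cond1), (analysis2, cond2)):
        recovered = analysis.class_by_symbol()
        for symbol, gt in sim.truth[cond].items():
            n_total += 1
            n_correct += recovered.get(symbol) == gt.cls
    class_accuracy = n_correct / n_total if n_total else float("nan")

    detected: dict[str, dict[str, str]] = {}
    for mark, quads in contrast.quadrants.items():
        for q in quads:
            detected.setdefault(q.symbol, {})[mark] = q.quadrant
    n_planted = 0
    n_found = 0
    for symbol, per_mark in sim.planted_quadrants.items():
        for mark, quadrant in per_mark.items():
            n_planted += 1
            n_found += detected.get(symbol, {}).get(mark) == quadrant
    sensitivity = n_found / n_planted if n_planted else float("nan")

    active = {c.symbol for c in analysis1.activity if c.active}
    k4 = analysis1.marked[MARK_H3K4ME3]
    symbols = {c.symbol for c in analysis1.classes}
    a = len(k4 & active)
    b = len(k4 - active)
    c = len((symbols - k4) & active)
    d = len(symbols - k4 - active)
    test = chi_square_2x2([[a, b], [c, d]])

    nf = analysis1.net_fractions.get(PAIR_K4_VS_K27)
    return {
        "class_accuracy": class_accuracy,
        "n_class_scored": n_total,
        "quadrant_sensitivity": sensitivity,
        "n_planted_quadrants": n_planted,
        "chi2_k4_vs_activity": test.chi2,
        "p_k4_vs_activity": test.p,
        "f_expressed_given_net_positive": (
            nf.f_expressed_given_net_positive if nf else float("nan")
        ),
        "f_expressed_given_net_nonpositive": (
            (1.0 - nf.f_silent_given_net_nonpositive)
            if nf and nf.f_silent_given_net_nonpositive is not None
            else float("nan")
        ),
    }
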