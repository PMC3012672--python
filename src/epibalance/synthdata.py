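"""Synthetic promoter tiling-array experiments with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* genes with non-overlapping 8 kb promoter windows (5.5 kb upstream to
  2.5 kb downstream of the TSS) tiled by ~41 probes at 200 bp spacing, plus
  a small fraction of intergenic decoy probes;
* per-gene mark combinations drawn from the eight classes; histone marks
  form contiguous enrichment islands while DNA methylation appears as a
  couple of sporadic high probes, so gene-level totals cross or miss the
  marked threshold (7) with a designed margin;
* log2 expression in [5, 16] generated from a linear link on the planted
  net intensity (activating minus repressive totals) plus Gaussian noise;
* an optional two-condition "EMT switch": a fraction of genes re-draw their
  mark class from a transition kernel biased toward H3K4me3 gain and DNAMe
  loss, with expression regenerated from the new truth.

Everything is deterministic under a fixed seed, and the planted truth
(classes, island coordinates, totals, expression means, switch quadrants) is
kept alongside the emitted files so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .arraydata import (
    EXPRESSION_CEILING,
    EXPRESSION_FLOOR,
    MARK_DNAME,
    MARK_H3K27ME3,
    MARK_H3K4ME3,
    MARKS,
    PROMOTER_DOWNSTREAM_BP,
    PROMOTER_UPSTREAM_BP,
    ExpressionTable,
    GeneModel,
    MarkTrack,
    ProbeRecord,
    write_expression,
    write_gene_annotation,
    write_probe_coords,
    write_track_values,
)
from .differential import (
    EXPRESSION_DELTA_THRESHOLD,
    MARK_DELTA_THRESHOLD,
    QUAD_DISCORDANT,
    QUAD_K27DOWN_EXPRUP,
    QUAD_K27UP_EXPRDOWN,
    QUAD_K4DOWN_EXPRDOWN,
    QUAD_K4UP_EXPRUP,
)
from .genescore import CLASS_NAMES

_CLASS_MARKS: dict[str, frozenset[str]] = {
    "none": frozenset(),
    "K4_only": frozenset({MARK_H3K4ME3}),
    "K27_only": frozenset({MARK_H3K27ME3}),
    "DNAMe_only": frozenset({MARK_DNAME}),
    "K4_K27": frozenset({MARK_H3K4ME3, MARK_H3K27ME3}),
    "K4_DNAMe": frozenset({MARK_H3K4ME3, MARK_DNAME}),
    "K27_DNAMe": frozenset({MARK_H3K27ME3, MARK_DNAME}),
    "trivalent": frozenset(MARKS),
}

#: Stationary class frequencies chosen so the three marks cover roughly 60%
#: (H3K4me3), 26% (H3K27me3) and 27% (DNAMe) of genes, with sizeable
#: bivalent groups.
DEFAULT_CLASS_PROBS: dict[str, float] = {
    "none": 0.25,
    "K4_only": 0.30,
    "K27_only": 0.08,
    "DNAMe_only": 0.07,
    "K4_K27": 0.10,
    "K4_DNAMe": 0.12,
    "K27_DNAMe": 0.03,
    "trivalent": 0.05,
}

#: Redraw distribution for switching genes: biased toward H3K4me3 gain
#: (class mass 0.76) and DNAMe loss (mass 0.17), with a mild H3K27me3 gain
#: (mass 0.37), so the two-condition contrast shows more histone-mark gains
#: than losses and a net DNA-methylation loss.
DEFAULT_SWITCH_PROBS: dict[str, float] = {
    "none": 0.10,
    "K4_only": 0.45,
    "K27_only": 0.10,
    "DNAMe_only": 0.02,
    "K4_K27": 0.18,
    "K4_DNAMe": 0.06,
    "K27_DNAMe": 0.02,
    "trivalent": 0.07,
}


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment.

    Island means and lengths are chosen so planted marked totals clear the
    gene-level threshold (7) with a margin of about 3 intensity units, and
    unmarked background totals stay below it with the same margin: histone
    islands of 6-12 probes at mean 1.8 give totals 10.8-21.6; the two
    sporadic DNAMe probes at mean 5.0 give totals near 10; background noise
    at sigma 0.25 keeps the clipped background sum over ~41 probes near 4.
    """

    n_genes: int = 2000
    genes_per_chrom: int = 500
    gene_spacing_bp: int = 25000
    probe_spacing_bp: int = 200
    probe_length_bp: int = 60
    decoy_fraction: float = 0.05
    class_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS)
    )
    island_len_min: int = 6
    island_len_max: int = 12
    dname_n_probes: int = 2
    island_mu: dict[str, float] = field(
        default_factory=lambda: {MARK_H3K4ME3: 1.8, MARK_H3K27ME3: 1.8, MARK_DNAME: 5.0}
    )
    background_sigma: float = 0.25
    beta0: float = 7.5
    beta_net: float = 0.35
    beta_dname_only: float = -0.15
    expr_noise_sigma: float = 0.8
    switch_fraction: float = 0.1
    switch_class_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SWITCH_PROBS)
    )
    conditions: tuple[str, str] = ("epithelial", "mesenchymal")
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.switch_fraction <= 1.0:
            raise ValueError("switch_fraction must lie in [0, 1]")
        for name, probs in (("class_probs", self.class_probs),
                            ("switch_class_probs", self.switch_class_probs)):
            if set(probs) != set(CLASS_NAMES):
                raise ValueError(f"{name} must cover exactly the 8 classes")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if self.n_tile_probes < 30:
            raise ValueError(
                "probe spacing too coarse: need >= 30 probes per gene window"
            )
        if not 0 < self.island_len_min <= self.island_len_max <= self.n_tile_probes:
            raise ValueError("invalid island length range")

    @property
    def window_len_bp(self) -> int:
        return PROMOTER_UPSTREAM_BP + PROMOTER_DOWNSTREAM_BP

    @property
    def n_tile_probes(self) -> int:
        """Probes tiling one window, both endpoints included (41 at 200 bp)."""
        return self.window_len_bp // self.probe_spacing_bp + 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)


@dataclass(frozen=True)
class IslandPlan:
    """Planted enrichment for one (gene, mark): probe indices and mean."""

    mark: str
    probe_indices: tuple[int, ...]
    mu: float

    @property
    def planted_total(self) -> float:
        return len(self.probe_indices) * self.mu


@dataclass
class GeneTruth:
    """Planted state of one gene in one condition."""

    symbol: str
    cls: str
    plans: dict[str, IslandPlan]
    expr_mean_raw: float = 0.0

    def planted_total(self, mark: str) -> float:
        plan = self.plans.get(mark)
        return plan.planted_total if plan is not None else 0.0

    @property
    def planted_net(self) -> float:
        return self.planted_total(MARK_H3K4ME3) - self.planted_total(MARK_H3K27ME3)

    @property
    def expr_mean(self) -> float:
        """Expression mean after clipping to the [5, 16] dynamic range."""
        return min(max(self.expr_mean_raw, EXPRESSION_FLOOR), EXPRESSION_CEILING)


@dataclass
class SimGenome:
    genes: list[GeneModel]
    probes: list[ProbeRecord]  # sorted by (chrom, start)
    gene_probe_ids: dict[str, list[str]]  # window tiling probes, 5' to 3' of coords
    decoy_ids: list[str]


@dataclass
class Simulation:
    """A complete two-condition synthetic experiment with its ground truth."""

    config: SimConfig
    genome: SimGenome
    truth: dict[str, dict[str, GeneTruth]]  # condition -> symbol -> truth
    tracks: dict[tuple[str, str], MarkTrack]  # (mark, condition) -> track
    expression: dict[str, ExpressionTable]
    switched: set[str]
    planted_quadrants: dict[str, dict[str, str]]  # symbol -> mark -> quadrant


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(cfg: SimConfig, rng: np.random.Generator) -> SimGenome:
    """Lay out genes and tiling probes on synthetic chromosomes.

    Genes sit on a regular grid (one per ``gene_spacing_bp``) so scoring
    regions never overlap; each window is tiled end to end at the probe
    spacing.  Decoy probes are placed in the guaranteed-intergenic gap
    between consecutive gene slots, exercising unmapped-probe reporting.
    """
    genes: list[GeneModel] = []
    probes: list[ProbeRecord] = []
    gene_probe_ids: dict[str, list[str]] = {}
    anchors: list[tuple[str, int]] = []

    n_tile = cfg.n_tile_probes
    for i in range(cfg.n_genes):
        chrom = f"chr{i // cfg.genes_per_chrom + 1}"
        slot = i % cfg.genes_per_chrom
        anchor = 100_000 + slot * cfg.gene_spacing_bp  # window start
        anchors.append((chrom, anchor))
        symbol = f"G{i:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        gene_len = int(rng.integers(2000, 10001))
        if strand == "+":
            tss = anchor + PROMOTER_UPSTREAM_BP
            gene_end = tss + gene_len
        else:
            tss = anchor + PROMOTER_DOWNSTREAM_BP
            gene_end = tss - gene_len
        genes.append(GeneModel(symbol, chrom, strand, tss, gene_end))

        ids = []
        for k in range(n_tile):
            # probes centered on the tile positions, so the probes at both
            # window endpoints overlap the (half-open) window
            center = anchor + k * cfg.probe_spacing_bp
            start = center - cfg.probe_length_bp // 2
            pid = f"p_{chrom}_{start:09d}"
            probes.append(ProbeRecord(pid, chrom, start, start + cfg.probe_length_bp))
            ids.append(pid)
        gene_probe_ids[symbol] = ids

    # Decoys go into [anchor + 16 kb, anchor + 17 kb): past any + strand gene
    # body (<= anchor + 15.5 kb) and clear of the next slot's - strand span
    # (>= anchor + 17.5 kb).
    n_decoy = int(round(cfg.decoy_fraction * len(probes)))
    max_per_gap = 1000 // cfg.probe_spacing_bp
    if n_decoy > max_per_gap * cfg.n_genes:
        raise ValueError("decoy_fraction too large for the intergenic gaps")
    decoy_ids: list[str] = []
    for j in range(n_decoy):
        chrom, anchor = anchors[j % cfg.n_genes]
        offset = (j // cfg.n_genes) * cfg.probe_spacing_bp
        pos = anchor + cfg.window_len_bp + 8000 + offset
        pid = f"d_{chrom}_{pos:09d}"
        probes.append(ProbeRecord(pid, chrom, pos, pos + cfg.probe_length_bp))
        decoy_ids.append(pid)

    chrom_order = {f"chr{c + 1}": c for c in range(-(-cfg.n_genes // cfg.genes_per_chrom))}
    probes.sort(key=lambda p: (chrom_order[p.chrom], p.start))
    return SimGenome(
        genes=genes, probes=probes, gene_probe_ids=gene_probe_ids, decoy_ids=decoy_ids
    )


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def _plan_islands(
    cfg: SimConfig, cls: str, rng: np.random.Generator
) -> dict[str, IslandPlan]:
    """Draw island placements for every mark of a gene's class.

    Histone marks get one contiguous island of 6-12 probes placed uniformly
    in the window; DNAMe gets a fixed small number of sporadic probes.
    """
    plans: dict[str, IslandPlan] = {}
    n_tile = cfg.n_tile_probes
    for mark in MARKS:  # fixed iteration order keeps the rng stream stable
        if mark not in _CLASS_MARKS[cls]:
            continue
        if mark == MARK_DNAME:
            idx = np.sort(rng.choice(n_tile, size=cfg.dname_n_probes, replace=False))
            indices = tuple(int(i) for i in idx)
        else:
            length = int(rng.integers(cfg.island_len_min, cfg.island_len_max + 1))
            start = int(rng.integers(0, n_tile - length + 1))
            indices = tuple(range(start, start + length))
        plans[mark] = IslandPlan(mark=mark, probe_indices=indices, mu=cfg.island_mu[mark])
    return plans


def _expr_mean_raw(cfg: SimConfig, truth: GeneTruth) -> float:
    dname_only_term = 0.0
    if MARK_H3K4ME3 not in truth.plans:
        dname_only_term = cfg.beta_dname_only * truth.planted_total(MARK_DNAME)
    return cfg.beta0 + cfg.beta_net * truth.planted_net + dname_only_term


def build_truth(
    cfg: SimConfig, classes: Mapping[str, str], rng: np.random.Generator
) -> dict[str, GeneTruth]:
    """Island plans and expression means for a per-gene class assignment."""
    truth: dict[str, GeneTruth] = {}
    for symbol in sorted(classes):
        cls = classes[symbol]
        gt = GeneTruth(symbol=symbol, cls=cls, plans=_plan_islands(cfg, cls, rng))
        gt.expr_mean_raw = _expr_mean_raw(cfg, gt)
        truth[symbol] = gt
    return truth


def apply_emt_switch(
    cfg: SimConfig, truth1: Mapping[str, GeneTruth], rng: np.random.Generator
) -> tuple[dict[str, GeneTruth], set[str]]:
    """Derive condition-2 truth by re-drawing a fraction of gene classes.

    Switching genes draw a new class from the biased transition kernel and
    re-plan all their islands; non-switching genes keep their condition-1
    plans exactly, so their condition-2 totals differ only by probe noise.
    """
    classes = list(CLASS_NAMES)
    probs = np.array([cfg.switch_class_probs[c] for c in classes])
    truth2: dict[str, GeneTruth] = {}
    switched: set[str] = set()
    for symbol in sorted(truth1):
        gt1 = truth1[symbol]
        if rng.random() < cfg.switch_fraction:
            switched.add(symbol)
            new_cls = classes[int(rng.choice(len(classes), p=probs))]
            gt2 = GeneTruth(
                symbol=symbol, cls=new_cls, plans=_plan_islands(cfg, new_cls, rng)
            )
            gt2.expr_mean_raw = _expr_mean_raw(cfg, gt2)
        else:
            gt2 = replace(gt1, plans=dict(gt1.plans))
        truth2[symbol] = gt2
    return truth2, switched


def planted_quadrants(
    cfg: SimConfig,
    truth1: Mapping[str, GeneTruth],
    truth2: Mapping[str, GeneTruth],
) -> dict[str, dict[str, str]]:
    """Ground-truth concordance quadrants implied by the planted deltas.

    A (gene, mark) pair receives a quadrant when the planted mark delta and
    the planted (clipped) expression delta both exceed their differential
    thresholds; the label follows the concordance rules (H3K4me3 with
    expression, H3K27me3 against it), with mismatched directions recorded as
    discordant.
    """
    quads: dict[str, dict[str, str]] = {}
    for symbol in truth1:
        gt1, gt2 = truth1[symbol], truth2[symbol]
        d_expr = gt2.expr_mean - gt1.expr_mean
        if abs(d_expr) <= EXPRESSION_DELTA_THRESHOLD:
            continue
        expr_up = d_expr > 0
        per_mark: dict[str, str] = {}
        for mark in (MARK_H3K4ME3, MARK_H3K27ME3):
            d_mark = gt2.planted_total(mark) - gt1.planted_total(mark)
            if abs(d_mark) <= MARK_DELTA_THRESHOLD:
                continue
            mark_up = d_mark > 0
            if mark == MARK_H3K4ME3:
                if mark_up and expr_up:
                    per_mark[mark] = QUAD_K4UP_EXPRUP
                elif not mark_up and not expr_up:
                    per_mark[mark] = QUAD_K4DOWN_EXPRDOWN
                else:
                    per_mark[mark] = QUAD_DISCORDANT
            else:
                if mark_up and not expr_up:
                    per_mark[mark] = QUAD_K27UP_EXPRDOWN
                elif not mark_up and expr_up:
                    per_mark[mark] = QUAD_K27DOWN_EXPRUP
                else:
                    per_mark[mark] = QUAD_DISCORDANT
        if per_mark:
            quads[symbol] = per_mark
    return quads


# ---------------------------------------------------------------------------
# realization
# ---------------------------------------------------------------------------

def realize_tracks(
    cfg: SimConfig,
    genome: SimGenome,
    truth: Mapping[str, GeneTruth],
    rng: np.random.Generator,
    condition: str,
) -> dict[str, MarkTrack]:
    """Draw probe-level log2 ratios for all three marks of one condition."""
    probe_index = {p.probe_id: i for i, p in enumerate(genome.probes)}
    n = len(genome.probes)
    tracks: dict[str, MarkTrack] = {}
    for mark in MARKS:
        values = rng.normal(0.0, cfg.background_sigma, size=n)
        for symbol in sorted(truth):
            plan = truth[symbol].plans.get(mark)
            if plan is None:
                continue
            ids = genome.gene_probe_ids[symbol]
            idx = [probe_index[ids[i]] for i in plan.probe_indices]
            values[idx] = rng.normal(plan.mu, cfg.background_sigma, size=len(idx))
        tracks[mark] = MarkTrack(
            mark=mark,
            condition=condition,
            values={p.probe_id: float(values[i]) for i, p in enumerate(genome.probes)},
        )
    return tracks


def sample_expression(
    cfg: SimConfig,
    truth: Mapping[str, GeneTruth],
    rng: np.random.Generator,
    condition: str,
) -> ExpressionTable:
    """Draw log2 expression from the linear net-intensity link plus noise."""
    values: dict[str, float] = {}
    for symbol in sorted(truth):
        raw = truth[symbol].expr_mean_raw + rng.normal(0.0, cfg.expr_noise_sigma)
        values[symbol] = float(
            min(max(raw, EXPRESSION_FLOOR), EXPRESSION_CEILING)
        )
    return ExpressionTable(condition=condition, values=values)


def simulate_experiment(cfg: SimConfig) -> Simulation:
    """Run the full two-condition generator under the config's seed."""
    ss = np.random.SeedSequence(cfg.seed)
    r_genome, r_class, r_truth, r_switch, r_t1, r_t2, r_e1, r_e2 = (
        np.random.default_rng(child) for child in ss.spawn(8)
    )
    genome = generate_genome(cfg, r_genome)
    class_names = list(CLASS_NAMES)
    probs = np.array([cfg.class_probs[c] for c in class_names])
    draws = r_class.choice(len(class_names), size=cfg.n_genes, p=probs)
    classes = {
        g.symbol: class_names[int(d)] for g, d in zip(genome.genes, draws)
    }
    cond1, cond2 = cfg.conditions
    truth1 = build_truth(cfg, classes, r_truth)
    truth2, switched = apply_emt_switch(cfg, truth1, r_switch)
    tracks: dict[tuple[str, str], MarkTrack] = {}
    for mark, track in realize_tracks(cfg, genome, truth1, r_t1, cond1).items():
        tracks[(mark, cond1)] = track
    for mark, track in realize_tracks(cfg, genome, truth2, r_t2, cond2).items():
        tracks[(mark, cond2)] = track
    expression = {
        cond1: sample_expression(cfg, truth1, r_e1, cond1),
        cond2: sample_expression(cfg, truth2, r_e2, cond2),
    }
    return Simulation(
        config=cfg,
        genome=genome,
        truth={cond1: truth1, cond2: truth2},
        tracks=tracks,
        expression=expression,
        switched=switched,
        planted_quadrants=planted_quadrants(cfg, truth1, truth2),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_simulation(sim: Simulation, outdir: str | Path) -> dict[str, Path]:
    """Emit all files of a simulation in the standard text dialects.

    Writes probe coordinates (BED4), gene annotation (BED6), one value TSV
    per (mark, condition), one expression TSV per condition, the planted
    truth table and the resolved config.  Byte-identical across runs for a
    fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["probes"] = outdir / "probes.bed"
    write_probe_coords(sim.genome.probes, paths["probes"])
    paths["genes"] = outdir / "genes.bed"
    write_gene_annotation(sim.genome.genes, paths["genes"])
    for (mark, cond), track in sorted(sim.tracks.items()):
        key = f"track_{mark}_{cond}"
        paths[key] = outdir / f"{mark}_{cond}.tsv"
        write_track_values(track.values, paths[key])
    for cond, expr in sorted(sim.expression.items()):
        key = f"expression_{cond}"
        paths[key] = outdir / f"expression_{cond}.tsv"
        write_expression(expr, paths[key])

    paths["truth"] = outdir / "truth.tsv"
    cond1, cond2 = sim.config.conditions
    with open(paths["truth"], "w", encoding="utf-8") as handle:
        cols = [
            "symbol", "class_1", "class_2", "switched",
            "k4_total_1", "k27_total_1", "dname_total_1",
            "k4_total_2", "k27_total_2", "dname_total_2",
            "expr_mean_1", "expr_mean_2", "quadrant_K4", "quadrant_K27",
        ]
        handle.write("\t".join(cols) + "\n")
        for symbol in sorted(sim.truth[cond1]):
            t1 = sim.truth[cond1][symbol]
            t2 = sim.truth[cond2][symbol]
            q = sim.planted_quadrants.get(symbol, {})
            row = [
                symbol, t1.cls, t2.cls, str(int(symbol in sim.switched)),
                f"{t1.planted_total(MARK_H3K4ME3):.6f}",
                f"{t1.planted_total(MARK_H3K27ME3):.6f}",
                f"{t1.planted_total(MARK_DNAME):.6f}",
                f"{t2.planted_total(MARK_H3K4ME3):.6f}",
                f"{t2.planted_total(MARK_H3K27ME3):.6f}",
                f"{t2.planted_total(MARK_DNAME):.6f}",
                f"{t1.expr_mean:.6f}",
                f"{t2.expr_mean:.6f}",
                q.get(MARK_H3K4ME3, "."),
                q.get(MARK_H3K27ME3, "."),
            ]
            handle.write("\t".join(row) + "\n")

    paths["config"] = outdir / "config.yaml"
    sim.config.to_yaml(paths["config"])
    return paths
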