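"""Domain types and I/O for promoter tiling-array epigenomics data.

The analysis works on three kinds of inputs, all plain tab-delimited text:

* probe-level mark tracks — one normalized log2 IP/control ratio per tiling
  probe, one track per (mark, condition);
* a gene annotation giving, per gene symbol, the strand-oriented scoring
  window around the transcription start site (5.5 kb upstream to 2.5 kb
  downstream) plus the annotated gene span;
* per-condition expression tables of log2 intensities clipped to [5, 16].

All genomic coordinates are 0-based, half-open.  Sources using 1-based fully
closed coordinates (e.g. GFF-style annotations) must be converted by the
caller before writing the BED dialects read here.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

MARK_H3K4ME3 = "H3K4me3"
MARK_H3K27ME3 = "H3K27me3"
MARK_DNAME = "DNAMe"
MARKS: tuple[str, ...] = (MARK_H3K4ME3, MARK_H3K27ME3, MARK_DNAME)

#: Promoter window extent around the TSS, strand-oriented (bp).
PROMOTER_UPSTREAM_BP = 5500
PROMOTER_DOWNSTREAM_BP = 2500

#: Expression log2 intensities are clipped into this range.
EXPRESSION_FLOOR = 5.0
EXPRESSION_CEILING = 16.0


class ParseError(ValueError):
    """A malformed record in an input file; message carries the line number."""


@dataclass(frozen=True)
class ProbeRecord:
    """One tiling probe with its genomic interval (0-based, half-open)."""

    probe_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"probe {self.probe_id}: start must be < end "
                f"({self.start} >= {self.end})"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class MarkTrack:
    """Per-probe log2 IP/control ratios for one (mark, condition).

    ``values`` holds only probes with a measured, finite ratio; probes present
    in the coordinate file but absent from the value file are listed in
    ``missing`` — they are excluded from every downstream sum and count, never
    imputed as zero.
    """

    mark: str
    condition: str
    values: dict[str, float]
    missing: frozenset[str] = frozenset()

    @property
    def probe_ids(self) -> frozenset[str]:
        """All probes of the track's coordinate set (measured or missing)."""
        return frozenset(self.values) | self.missing


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-oriented promoter scoring window.

    ``tss`` is the transcription start site; ``gene_end`` the opposite end of
    the annotated span (``gene_end`` < ``tss`` on the minus strand).
    """

    symbol: str
    chrom: str
    strand: str
    tss: int
    gene_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.symbol}: unknown strand {self.strand!r}")

    @property
    def window(self) -> tuple[int, int]:
        """Half-open promoter window: 5.5 kb upstream to 2.5 kb downstream."""
        if self.strand == "+":
            return (self.tss - PROMOTER_UPSTREAM_BP, self.tss + PROMOTER_DOWNSTREAM_BP)
        return (self.tss - PROMOTER_DOWNSTREAM_BP, self.tss + PROMOTER_UPSTREAM_BP)

    @property
    def scoring_region(self) -> tuple[int, int]:
        """Union of the promoter window and the annotated gene span.

        Both intervals contain the TSS, so the union is one interval.  Probes
        in the gene body beyond the +2.5 kb window edge still count toward
        gene-level totals.
        """
        span_lo = min(self.tss, self.gene_end)
        span_hi = max(self.tss, self.gene_end)
        w_lo, w_hi = self.window
        return (min(w_lo, span_lo), max(w_hi, span_hi))


@dataclass
class ExpressionTable:
    """Per-condition log2 expression values, clipped to [5, 16]."""

    condition: str
    values: dict[str, float]


@dataclass
class ProbeGeneMap:
    """Probe-to-gene assignments by interval overlap with scoring regions.

    A probe overlapping two genes' regions appears under both; probes
    overlapping none are counted in ``n_unmapped``.
    """

    assignments: dict[str, frozenset[str]]
    n_unmapped: int

    def gene_to_probes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = defaultdict(set)
        for probe_id, symbols in self.assignments.items():
            for sym in symbols:
                out[sym].add(probe_id)
        return dict(out)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if line.strip():
                yield lineno, line


def read_probe_coords(path: str | Path) -> list[ProbeRecord]:
    """Read probe coordinates from BED4 (chrom, start, end, probe_id)."""
    probes: list[ProbeRecord] = []
    seen: set[str] = set()
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 BED fields, got {len(fields)}")
        chrom, start_s, end_s, probe_id = fields[:4]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        if probe_id in seen:
            raise ParseError(f"{path}:{lineno}: duplicate probe_id {probe_id!r}")
        seen.add(probe_id)
        try:
            probes.append(ProbeRecord(probe_id, chrom, start, end))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return probes


def read_track_values(path: str | Path) -> dict[str, float]:
    """Read a 2-column TSV (probe_id, log2 ratio) with a required header."""
    values: dict[str, float] = {}
    first = True
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if first:
            first = False
            if fields[0] != "probe_id":
                raise ParseError(
                    f"{path}:{lineno}: missing header line (expected 'probe_id\\t...')"
                )
            continue
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        probe_id, value_s = fields[0], fields[1]
        if probe_id in values:
            raise ParseError(f"{path}:{lineno}: duplicate probe_id {probe_id!r}")
        try:
            value = float(value_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric ratio {value_s!r}") from exc
        if not math.isfinite(value):
            raise ParseError(f"{path}:{lineno}: non-finite ratio for {probe_id!r}")
        values[probe_id] = value
    return values


def read_probe_track(
    coords_path: str | Path,
    values_path: str | Path,
    mark: str,
    condition: str,
) -> MarkTrack:
    """Assemble a :class:`MarkTrack` from a coordinate file and a value file.

    Probes present in the coordinates but absent from the value file are
    recorded as ``missing``.  Values for probe ids not in the coordinate file
    are an error (the track and its array design must agree).
    """
    coords = read_probe_coords(coords_path)
    coord_ids = {p.probe_id for p in coords}
    values = read_track_values(values_path)
    orphans = set(values) - coord_ids
    if orphans:
        example = sorted(orphans)[0]
        raise ParseError(
            f"{values_path}: {len(orphans)} probe id(s) not in the coordinate "
            f"file (e.g. {example!r})"
        )
    missing = frozenset(coord_ids - set(values))
    return MarkTrack(mark=mark, condition=condition, values=values, missing=missing)


def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Read genes from BED6 (chrom, txStart, txEnd, symbol, score, strand).

    The TSS is ``txStart`` on the plus strand and ``txEnd`` on the minus
    strand; the scoring window is computed strand-oriented.
    """
    genes: list[GeneModel] = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: expected 6 BED fields, got {len(fields)}")
        chrom, start_s, end_s, symbol, _score, strand = fields[:6]
        try:
            tx_start, tx_end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        if tx_start >= tx_end:
            raise ParseError(
                f"{path}:{lineno}: txStart >= txEnd for {symbol!r} "
                f"({tx_start} >= {tx_end})"
            )
        if strand == "+":
            tss, gene_end = tx_start, tx_end
        elif strand == "-":
            tss, gene_end = tx_end, tx_start
        else:
            raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
        genes.append(GeneModel(symbol, chrom, strand, tss, gene_end))
    return genes


def read_expression(path: str | Path, condition: str) -> ExpressionTable:
    """Read a 2-column TSV (symbol, log2 value) with a required header.

    Values are clipped into [5, 16].  A symbol listed more than once keeps its
    maximum value: a gene counts as expressed if any of its probes says so.
    """
    values: dict[str, float] = {}
    first = True
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if first:
            first = False
            if fields[0] != "symbol":
                raise ParseError(
                    f"{path}:{lineno}: missing header line (expected 'symbol\\t...')"
                )
            continue
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        symbol, value_s = fields[0], fields[1]
        try:
            value = float(value_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric value {value_s!r}") from exc
        if not math.isfinite(value):
            raise ParseError(f"{path}:{lineno}: non-finite value for {symbol!r}")
        value = min(max(value, EXPRESSION_FLOOR), EXPRESSION_CEILING)
        if symbol in values:
            values[symbol] = max(values[symbol], value)
        else:
            values[symbol] = value
    return ExpressionTable(condition=condition, values=values)


# ---------------------------------------------------------------------------
# writers (same dialects; 6-decimal fixed formatting for exact round-trips)
# ---------------------------------------------------------------------------

def write_probe_coords(probes: Sequence[ProbeRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for p in probes:
            handle.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.probe_id}\n")


def write_track_values(values: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("probe_id\tlog2ratio\n")
        for probe_id, value in values.items():
            handle.write(f"{probe_id}\t{value:.6f}\n")


def write_gene_annotation(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for g in genes:
            tx_start = min(g.tss, g.gene_end)
            tx_end = max(g.tss, g.gene_end)
            handle.write(f"{g.chrom}\t{tx_start}\t{tx_end}\t{g.symbol}\t0\t{g.strand}\n")


def write_expression(expr: ExpressionTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("symbol\tlog2_expression\n")
        for symbol, value in expr.values.items():
            handle.write(f"{symbol}\t{value:.6f}\n")


# ---------------------------------------------------------------------------
# mapping and universe
# ---------------------------------------------------------------------------

def map_probes_to_genes(
    probes: Sequence[ProbeRecord], genes: Sequence[GeneModel]
) -> ProbeGeneMap:
    """Assign probes to genes by interval overlap with scoring regions.

    The assignment is deterministic and independent of input order: a probe is
    assigned to exactly the set of genes whose scoring region its interval
    overlaps (half-open semantics).
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        lo, hi = g.scoring_region
        trees[g.chrom].addi(lo, hi, g.symbol)
    assignments: dict[str, frozenset[str]] = {}
    n_unmapped = 0
    for p in probes:
        tree = trees.get(p.chrom)
        hits = tree.overlap(p.start, p.end) if tree is not None else ()
        symbols = frozenset(iv.data for iv in hits)
        if symbols:
            assignments[p.probe_id] = symbols
        else:
            n_unmapped += 1
    return ProbeGeneMap(assignments=assignments, n_unmapped=n_unmapped)


def intersect_gene_universe(
    expr: ExpressionTable, genes: Sequence[GeneModel]
) -> set[str]:
    """Symbols covered by both the expression table and the annotation.

    All downstream per-gene statistics restrict to this universe.  An empty
    intersection signals mismatched annotations and raises.
    """
    universe = set(expr.values) & {g.symbol for g in genes}
    if not universe:
        raise ValueError(
            "empty gene universe: expression table and annotation share no symbols"
        )
    return universe
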