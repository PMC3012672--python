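"""Gene-level mark scoring, mark-combination classes and net intensity.

A gene's *total intensity* for a mark is the sum of its assigned probes'
log2 ratios with negative values clipped to zero; genes whose total is
strictly above 7 are *marked*.  Genes are then partitioned per condition into
the eight combinations of the three marks (H3K4me3, H3K27me3, DNAMe), and for
bivalently marked genes a signed *net intensity* balances the activating
H3K4me3 total (positive) against the repressive H3K27me3 or DNAMe total
(negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .arraydata import (
    MARK_DNAME,
    MARK_H3K27ME3,
    MARK_H3K4ME3,
    MarkTrack,
    ProbeGeneMap,
)
from .probecall import SIGNIFICANCE_THRESHOLD

TOTAL_INTENSITY_THRESHOLD = 7.0

CLASS_NONE = "none"
CLASS_K4_ONLY = "K4_only"
CLASS_K27_ONLY = "K27_only"
CLASS_DNAME_ONLY = "DNAMe_only"
CLASS_K4_K27 = "K4_K27"
CLASS_K4_DNAME = "K4_DNAMe"
CLASS_K27_DNAME = "K27_DNAMe"
CLASS_TRIVALENT = "trivalent"
CLASS_NAMES: tuple[str, ...] = (
    CLASS_NONE,
    CLASS_K4_ONLY,
    CLASS_K27_ONLY,
    CLASS_DNAME_ONLY,
    CLASS_K4_K27,
    CLASS_K4_DNAME,
    CLASS_K27_DNAME,
    CLASS_TRIVALENT,
)

PAIR_K4_VS_K27 = "K4_vs_K27"
PAIR_K4_VS_DNAME = "K4_vs_DNAMe"


@dataclass(frozen=True)
class GeneMarkScore:
    symbol: str
    mark: str
    condition: str
    total_intensity: float
    n_significant_probes: int
    marked: bool


@dataclass(frozen=True)
class MarkClass:
    symbol: str
    condition: str
    cls: str


@dataclass(frozen=True)
class NetIntensity:
    """Signed balance of activating vs repressive totals for one gene."""

    symbol: str
    condition: str
    pair: str
    positive: float  # H3K4me3 total (>= 0)
    negative: float  # -1 x repressive total (<= 0)

    @property
    def net(self) -> float:
        return self.positive + self.negative


def total_gene_intensity(
    track: MarkTrack,
    probe_gene_map: ProbeGeneMap,
    universe: Iterable[str],
    threshold: float = TOTAL_INTENSITY_THRESHOLD,
    sig_threshold: float = SIGNIFICANCE_THRESHOLD,
    probe_mask: set[str] | None = None,
) -> list[GeneMarkScore]:
    """Score every universe gene on one track.

    Negative probe values count as zero; missing probes are excluded, not
    imputed.  ``probe_mask``, if given, restricts scoring to those probe ids
    (e.g. to score over bound probes only instead of all probes).  Genes with
    no assigned probe score 0 and are unmarked.
    """
    gene_probes = probe_gene_map.gene_to_probes()
    scores: list[GeneMarkScore] = []
    for symbol in sorted(set(universe)):
        total = 0.0
        n_sig = 0
        for probe_id in gene_probes.get(symbol, ()):
            if probe_mask is not None and probe_id not in probe_mask:
                continue
            value = track.values.get(probe_id)
            if value is None:  # missing probe
                continue
            total += max(value, 0.0)
            if value > sig_threshold:
                n_sig += 1
        scores.append(
            GeneMarkScore(
                symbol=symbol,
                mark=track.mark,
                condition=track.condition,
                total_intensity=total,
                n_significant_probes=n_sig,
                marked=total > threshold,
            )
        )
    return scores


def scores_by_symbol(scores: Sequence[GeneMarkScore]) -> dict[str, GeneMarkScore]:
    return {s.symbol: s for s in scores}


def marked_genes(scores: Sequence[GeneMarkScore]) -> set[str]:
    """Genes whose total intensity is strictly above the marked threshold."""
    return {s.symbol for s in scores if s.marked}


def _class_of(in_k4: bool, in_k27: bool, in_dname: bool) -> str:
    key = (in_k4, in_k27, in_dname)
    return {
        (False, False, False): CLASS_NONE,
        (True, False, False): CLASS_K4_ONLY,
        (False, True, False): CLASS_K27_ONLY,
        (False, False, True): CLASS_DNAME_ONLY,
        (True, True, False): CLASS_K4_K27,
        (True, False, True): CLASS_K4_DNAME,
        (False, True, True): CLASS_K27_DNAME,
        (True, True, True): CLASS_TRIVALENT,
    }[key]


def classify_marks(
    k4: set[str],
    k27: set[str],
    dname: set[str],
    universe: set[str],
    condition: str = "",
) -> list[MarkClass]:
    """Assign each universe gene its unique mark-combination class.

    The eight classes partition the universe.  Marked sets must be subsets of
    the universe.
    """
    for name, marked in ((MARK_H3K4ME3, k4), (MARK_H3K27ME3, k27), (MARK_DNAME, dname)):
        stray = marked - universe
        if stray:
            example = sorted(stray)[0]
            raise ValueError(
                f"{name} marked set contains {len(stray)} gene(s) outside the "
                f"universe (e.g. {example!r})"
            )
    return [
        MarkClass(symbol=g, condition=condition, cls=_class_of(g in k4, g in k27, g in dname))
        for g in sorted(universe)
    ]


def genes_in_classes(classes: Sequence[MarkClass], *cls_names: str) -> set[str]:
    wanted = set(cls_names)
    return {c.symbol for c in classes if c.cls in wanted}


# Convenience groups matching the analysis' gene-group vocabulary.  "Bivalent"
# groups include trivalent genes (marked by both members of the pair,
# regardless of the third mark); "DNAMe without H3K4me3" allows H3K27me3
# co-marking, while the strict DNAMe-only class is exposed separately.

def bivalent_k4_k27_genes(classes: Sequence[MarkClass]) -> set[str]:
    return genes_in_classes(classes, CLASS_K4_K27, CLASS_TRIVALENT)


def bivalent_k4_dname_genes(classes: Sequence[MarkClass]) -> set[str]:
    return genes_in_classes(classes, CLASS_K4_DNAME, CLASS_TRIVALENT)


def dname_without_k4_genes(classes: Sequence[MarkClass]) -> set[str]:
    return genes_in_classes(classes, CLASS_DNAME_ONLY, CLASS_K27_DNAME)


def net_intensity(
    k4_scores: Sequence[GeneMarkScore],
    repressive_scores: Sequence[GeneMarkScore],
    pair: str,
    genes: Iterable[str],
) -> list[NetIntensity]:
    """Net intensity (H3K4me3 total minus repressive total) per gene.

    ``genes`` is normally the bivalent group of the pair; every gene must be
    scored on both tracks.
    """
    if pair not in (PAIR_K4_VS_K27, PAIR_K4_VS_DNAME):
        raise ValueError(f"unknown pair {pair!r}")
    k4_by = scores_by_symbol(k4_scores)
    rep_by = scores_by_symbol(repressive_scores)
    nets: list[NetIntensity] = []
    for symbol in sorted(set(genes)):
        if symbol not in k4_by or symbol not in rep_by:
            raise ValueError(f"gene {symbol!r} is missing a score for pair {pair}")
        k4 = k4_by[symbol]
        rep = rep_by[symbol]
        nets.append(
            NetIntensity(
                symbol=symbol,
                condition=k4.condition,
                pair=pair,
                positive=k4.total_intensity,
                negative=-rep.total_intensity,
            )
        )
    return nets


def aggregate_net_sums(nets: Sequence[NetIntensity]) -> tuple[float, float]:
    """(sum of positive components, sum of negative components) over a group.

    The negative sum is reported as a negative number; an empty group yields
    (0, 0).
    """
    sum_pos = sum(n.positive for n in nets)
    sum_neg = sum(n.negative for n in nets)
    return (sum_pos, sum_neg)
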