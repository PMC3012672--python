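"""Probe-level co-modification: bivalent probes, clustered vs sporadic.

A *bivalent probe* carries significant intensity (>1) in both tracks of a
mark pair within the same condition.  A gene with at least 3 bivalent probes
of a pair carries *clustered* co-modification; genes with 1-2 bivalent probes
are *sporadic*.  Trivalent probes (significant in all three marks) are
reported separately and counted in each pairwise tally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .arraydata import MarkTrack, ProbeGeneMap
from .probecall import SIGNIFICANCE_THRESHOLD, significant_probes

PAIR_NAMES: dict[frozenset[str], str] = {
    frozenset({"H3K4me3", "H3K27me3"}): "K4_K27",
    frozenset({"H3K4me3", "DNAMe"}): "K4_DNAMe",
    frozenset({"H3K27me3", "DNAMe"}): "K27_DNAMe",
}

CLUSTER_MIN_PROBES = 3


@dataclass(frozen=True)
class BivalentProbe:
    probe_id: str
    pair: str
    condition: str


@dataclass(frozen=True)
class BivalentGeneSummary:
    symbol: str
    pair: str
    n_bivalent_probes: int
    clustered: bool


def bivalent_probes(
    track_a: MarkTrack,
    track_b: MarkTrack,
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> list[BivalentProbe]:
    """Probes significant (strictly > threshold) in both tracks of a pair.

    The two tracks must share one probe coordinate set and one condition;
    the result is symmetric in the order of the tracks.
    """
    if track_a.condition != track_b.condition:
        raise ValueError(
            f"condition mismatch: {track_a.condition!r} vs {track_b.condition!r}"
        )
    if track_a.probe_ids != track_b.probe_ids:
        raise ValueError("tracks do not share a probe coordinate set")
    pair = PAIR_NAMES.get(frozenset({track_a.mark, track_b.mark}))
    if pair is None:
        raise ValueError(f"no pair defined for marks {track_a.mark}/{track_b.mark}")
    both = significant_probes(track_a, threshold) & significant_probes(track_b, threshold)
    return [
        BivalentProbe(probe_id=pid, pair=pair, condition=track_a.condition)
        for pid in sorted(both)
    ]


def trivalent_probes(
    k4: MarkTrack,
    k27: MarkTrack,
    dname: MarkTrack,
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> set[str]:
    """Probes significant in all three marks of one condition."""
    return (
        significant_probes(k4, threshold)
        & significant_probes(k27, threshold)
        & significant_probes(dname, threshold)
    )


def clustered_bivalent_genes(
    biv: Sequence[BivalentProbe],
    probe_gene_map: ProbeGeneMap,
    min_probes: int = CLUSTER_MIN_PROBES,
) -> list[BivalentGeneSummary]:
    """Per-gene bivalent-probe counts with the clustered/sporadic flag.

    A probe mapping to several genes counts for each of them; probes are
    counted over the full scoring region (consistent with gene scoring).
    Only genes with at least one bivalent probe are listed.
    """
    counts: dict[tuple[str, str], int] = {}
    for bp in biv:
        for symbol in probe_gene_map.assignments.get(bp.probe_id, ()):
            key = (symbol, bp.pair)
            counts[key] = counts.get(key, 0) + 1
    return [
        BivalentGeneSummary(
            symbol=symbol,
            pair=pair,
            n_bivalent_probes=n,
            clustered=n >= min_probes,
        )
        for (symbol, pair), n in sorted(counts.items())
    ]


def comod_summary(
    per_pair: Mapping[str, tuple[Sequence[BivalentProbe], Sequence[BivalentGeneSummary]]],
) -> pd.DataFrame:
    """Aggregate bivalent-probe and clustered/sporadic-gene counts per pair.

    ``per_pair`` maps a pair label to (bivalent probes, per-gene summaries)
    for one condition; the result has one row per pair.
    """
    rows = []
    for pair, (probes, summaries) in per_pair.items():
        n_clustered = sum(1 for s in summaries if s.clustered)
        rows.append(
            {
                "pair": pair,
                "n_bivalent_probes_total": len(probes),
                "n_clustered_genes": n_clustered,
                "n_sporadic_genes": len(summaries) - n_clustered,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["pair", "n_bivalent_probes_total", "n_clustered_genes", "n_sporadic_genes"],
    )
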