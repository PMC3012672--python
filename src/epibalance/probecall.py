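"""Per-probe significance calls and the neighborhood "bound" model.

Two probe-level calls are made on a track of normalized log2 IP/control
ratios:

* *significant*: ratio strictly above 1 (a fixed intensity rule);
* *bound*: a neighborhood call in the style of per-array sliding-window peak
  models for tiling arrays.  Probes within 1000 bp (midpoint to midpoint) of
  the central probe are its neighbors; the central probe's ratio and the mean
  of the neighborhood are each referred to a Gaussian null, and a probe is
  bound iff P(Xbar) < 0.001, its own P(X) < 0.001, and at least one neighbor
  has P(X) < 0.1.  Probes with no neighbor are never bound.

The null is estimated robustly (median / 1.4826*MAD) because enriched probes
inflate naive moments.  The neighborhood mean is tested against
Normal(mu, sigma/sqrt(k)) with k the number of averaged probes; the
neighborhood average is unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .arraydata import MarkTrack, ProbeRecord

SIGNIFICANCE_THRESHOLD = 1.0
NEIGHBOR_MAX_DIST_BP = 1000
P_BOUND = 1e-3
P_NEIGHBOR = 0.1


@dataclass(frozen=True)
class NullModel:
    """Location/scale of a track's null log2-ratio distribution."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class ProbeCall:
    probe_id: str
    log2ratio: float
    p_x: float
    xbar: float
    p_xbar: float
    n_neighbors: int
    significant: bool
    bound: bool


def significant_probes(track: MarkTrack, threshold: float = SIGNIFICANCE_THRESHOLD) -> set[str]:
    """Probes with ratio strictly greater than ``threshold``."""
    return {pid for pid, v in track.values.items() if v > threshold}


def estimate_null(track: MarkTrack, min_probes: int = 100) -> NullModel:
    """Robust null: mu = median, sigma = 1.4826 x MAD of the log2 ratios."""
    vals = np.fromiter(track.values.values(), dtype=float)
    if vals.size < min_probes:
        raise ValueError(f"need at least {min_probes} probes, got {vals.size}")
    mu = float(np.median(vals))
    mad = float(np.median(np.abs(vals - mu)))
    if mad == 0.0:
        raise ValueError("degenerate track: MAD of log2 ratios is zero")
    return NullModel(mu=mu, sigma=1.4826 * mad)


def probe_pvalue(track: MarkTrack, null: NullModel) -> dict[str, float]:
    """Upper-tail probability of each probe's ratio under the Gaussian null."""
    ids = list(track.values)
    vals = np.fromiter((track.values[i] for i in ids), dtype=float)
    p = norm.sf((vals - null.mu) / null.sigma)
    return dict(zip(ids, p.tolist()))


def neighborhood_bound_call(
    track: MarkTrack,
    probes: Sequence[ProbeRecord],
    null: NullModel,
    max_dist: int = NEIGHBOR_MAX_DIST_BP,
) -> list[ProbeCall]:
    """Neighborhood bound calls for every measured probe.

    ``probes`` must be sorted by start within each chromosome (chromosome
    blocks may appear in any order); unsorted input raises.  Probes without a
    measured value are skipped entirely — they receive no call and do not
    contribute to any neighborhood mean.
    """
    measured = [p for p in probes if p.probe_id in track.values]
    by_chrom: dict[str, list[ProbeRecord]] = {}
    for p in measured:
        by_chrom.setdefault(p.chrom, []).append(p)

    calls: list[ProbeCall] = []
    for chrom, plist in by_chrom.items():
        starts = np.array([p.start for p in plist])
        if np.any(np.diff(starts) < 0):
            raise ValueError(f"probes on {chrom} are not sorted by start")
        mids = np.array([p.midpoint for p in plist])
        vals = np.array([track.values[p.probe_id] for p in plist])

        z = (vals - null.mu) / null.sigma
        p_x = norm.sf(z)

        left = np.searchsorted(mids, mids - max_dist, side="left")
        right = np.searchsorted(mids, mids + max_dist, side="right")
        k = right - left

        csum = np.concatenate(([0.0], np.cumsum(vals)))
        xbar = (csum[right] - csum[left]) / k
        p_xbar = norm.sf((xbar - null.mu) * np.sqrt(k) / null.sigma)

        weak = (p_x < P_NEIGHBOR).astype(np.int64)
        cweak = np.concatenate(([0], np.cumsum(weak)))
        has_weak_neighbor = (cweak[right] - cweak[left] - weak) >= 1

        bound = (k >= 2) & (p_xbar < P_BOUND) & (p_x < P_BOUND) & has_weak_neighbor
        sig = vals > SIGNIFICANCE_THRESHOLD

        for i, p in enumerate(plist):
            calls.append(
                ProbeCall(
                    probe_id=p.probe_id,
                    log2ratio=float(vals[i]),
                    p_x=float(p_x[i]),
                    xbar=float(xbar[i]),
                    p_xbar=float(p_xbar[i]),
                    n_neighbors=int(k[i]) - 1,
                    significant=bool(sig[i]),
                    bound=bool(bound[i]),
                )
            )
    return calls


def bound_fraction(calls: Sequence[ProbeCall]) -> float:
    """Fraction of called probes that are bound (0.0 for an empty list)."""
    if not calls:
        return 0.0
    return sum(c.bound for c in calls) / len(calls)
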