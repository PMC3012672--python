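"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (all-pairs scans, explicit counting,
sort-based medians) and shares no code with the package internals.
"""

from __future__ import annotations


def brute_force_probe_gene_map(probes, genes):
    """All-pairs interval-overlap scan (half-open intervals)."""
    assignments = {}
    for p in probes:
        hits = set()
        for g in genes:
            lo, hi = g.scoring_region
            if g.chrom == p.chrom and p.start < hi and lo < p.end:
                hits.add(g.symbol)
        if hits:
            assignments[p.probe_id] = frozenset(hits)
    return assignments


def brute_force_totals(track, assignments, universe, threshold=7.0, sig=1.0):
    """Per-gene loop over every probe of the track."""
    totals = {}
    for symbol in universe:
        total = 0.0
        n_sig = 0
        for probe_id, genes in assignments.items():
            if symbol not in genes or probe_id not in track.values:
                continue
            v = track.values[probe_id]
            total += v if v > 0 else 0.0
            if v > sig:
                n_sig += 1
        totals[symbol] = (total, n_sig, total > threshold)
    return totals


def brute_force_bivalent(track_a, track_b, threshold=1.0):
    """Significant-in-both probe ids computed without set algebra helpers."""
    out = set()
    for probe_id, va in track_a.values.items():
        vb = track_b.values.get(probe_id)
        if vb is None:
            continue
        if va > threshold and vb > threshold:
            out.add(probe_id)
    return out


def brute_force_median(values):
    """Sort-based median."""
    vals = sorted(values)
    n = len(vals)
    mid = n // 2
    if n % 2:
        return vals[mid]
    return 0.5 * (vals[mid - 1] + vals[mid])


def brute_force_net_fractions(nets, active_by):
    """Explicit counting of the four conditional activity/net-sign fractions."""
    pos = [n for n in nets if n.net > 0]
    nonpos = [n for n in nets if n.net <= 0]
    act = [n for n in nets if active_by[n.symbol]]
    sil = [n for n in nets if not active_by[n.symbol]]

    def frac(subset, pred):
        return sum(pred(n) for n in subset) / len(subset) if subset else None

    return {
        "f_expressed_given_net_positive": frac(pos, lambda n: active_by[n.symbol]),
        "f_silent_given_net_nonpositive": frac(nonpos, lambda n: not active_by[n.symbol]),
        "f_net_positive_given_expressed": frac(act, lambda n: n.net > 0),
        "f_net_nonpositive_given_silent": frac(sil, lambda n: n.net <= 0),
    }


def chi2_margin_formula(a, b, c, d):
    """Pearson chi-square via the closed form (ad-bc)^2 N / (margin product)."""
    n = a + b + c + d
    return (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
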