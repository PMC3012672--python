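"""Differential marks and expression between the two conditions.

Computes per-gene deltas of mark totals (differential when |delta| > 5) and
of expression (|delta| > 2), the concordance quadrants joining them, and the
top-100 epigenetically changed genes.
"""

from __future__ import annotations

import argparse
from collections import Counter
from pathlib import Path

import pandas as pd

from epibalance import (
    MARKS,
    intersect_gene_universe,
    map_probes_to_genes,
    top_changed_genes,
)
from epibalance.pipeline import analyse_condition, contrast_conditions, load_experiment


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=Path("results/sim"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--top", type=int, default=100)
    args = parser.parse_args()

    inputs = load_experiment(args.sim)
    pgmap = map_probes_to_genes(inputs.probes, inputs.genes)
    cond1, cond2 = inputs.conditions
    universe = intersect_gene_universe(inputs.expression[cond1], inputs.genes)
    a1, a2 = (
        analyse_condition({m: inputs.tracks[(m, c)] for m in MARKS},
                          inputs.expression[c], pgmap, universe, c)
        for c in (cond1, cond2)
    )
    contrast = contrast_conditions(a1, a2, inputs.expression[cond1],
                                   inputs.expression[cond2])

    args.out.mkdir(parents=True, exist_ok=True)
    delta_rows = []
    for mark, deltas in contrast.mark_deltas.items():
        up = sum(d.call == "increased" for d in deltas)
        down = sum(d.call == "decreased" for d in deltas)
        print(f"{mark}: {up} genes increased, {down} decreased ({cond1} -> {cond2})")
        delta_rows += [{"symbol": d.symbol, "quantity": d.quantity,
                        "delta": d.delta, "call": d.call} for d in deltas]
    up = sum(d.call == "increased" for d in contrast.expr_deltas)
    down = sum(d.call == "decreased" for d in contrast.expr_deltas)
    print(f"expression: {up} up-regulated, {down} down-regulated")
    delta_rows += [{"symbol": d.symbol, "quantity": d.quantity,
                    "delta": d.delta, "call": d.call} for d in contrast.expr_deltas]
    pd.DataFrame(delta_rows).to_csv(args.out / "deltas.tsv", sep="\t",
                                    index=False, float_format="%.6f")

    quad_rows = []
    for mark, quads in contrast.quadrants.items():
        counts = Counter(q.quadrant for q in quads)
        print(f"{mark} concordance quadrants: "
              + ", ".join(f"{q}={n}" for q, n in sorted(counts.items())))
        quad_rows += [{"symbol": q.symbol, "mark": mark, "quadrant": q.quadrant}
                      for q in quads]
    pd.DataFrame(quad_rows).to_csv(args.out / "quadrants.tsv", sep="\t", index=False)

    top_rows = []
    for mark in ("H3K4me3", "H3K27me3"):
        for rank, d in enumerate(
            top_changed_genes(contrast.mark_deltas[mark], n=args.top), start=1
        ):
            top_rows.append({"mark": mark, "rank": rank, "symbol": d.symbol,
                             "delta": d.delta, "call": d.call})
    pd.DataFrame(top_rows).to_csv(args.out / "top_changed_genes.tsv", sep="\t",
                                  index=False, float_format="%.6f")
    print(f"wrote deltas.tsv, quadrants.tsv, top_changed_genes.tsv under {args.out}")


if __name__ == "__main__":
    main()
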