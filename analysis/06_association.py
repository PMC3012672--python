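"""Mark/activity association report and recovery against planted truth.

Tabulates, per condition, the fraction of expressed genes carrying each
mark, group medians, chi-square tests of mark status vs activity, and the
net-intensity conditional fractions for the bivalent groups.  Because the
inputs are simulated, the script also scores class recovery and planted
concordance-quadrant sensitivity against truth.tsv.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from epibalance import MARKS, intersect_gene_universe, map_probes_to_genes
from epibalance.pipeline import analyse_condition, contrast_conditions, load_experiment


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=Path("results/sim"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    inputs = load_experiment(args.sim)
    pgmap = map_probes_to_genes(inputs.probes, inputs.genes)
    cond1, cond2 = inputs.conditions
    universe = intersect_gene_universe(inputs.expression[cond1], inputs.genes)
    analyses = {
        c: analyse_condition({m: inputs.tracks[(m, c)] for m in MARKS},
                             inputs.expression[c], pgmap, universe, c)
        for c in (cond1, cond2)
    }

    from epibalance import mark_activity_report

    args.out.mkdir(parents=True, exist_ok=True)
    for cond, analysis in analyses.items():
        report = mark_activity_report(
            analysis.classes, analysis.activity, inputs.expression[cond],
            nets=analysis.nets,
        )
        for name, df in report.items():
            df.to_csv(args.out / f"report_{name}_{cond}.tsv", sep="\t",
                      index=False, float_format="%.4g")
        marks = report["marks"].set_index("mark")
        print(f"{cond}: {100 * marks.loc['H3K4me3', 'f_marked_expressed']:.0f}% of "
              f"H3K4me3-marked genes expressed (chi2={marks.loc['H3K4me3', 'chi2']:.0f}, "
              f"p={marks.loc['H3K4me3', 'p']:.2g}); DNAMe-marked "
              f"{100 * marks.loc['DNAMe', 'f_marked_expressed']:.0f}% expressed")
        if "net" in report:
            for _, row in report["net"].iterrows():
                print(f"{cond} {row['pair']}: "
                      f"{100 * row['f_net_positive_given_expressed']:.0f}% of expressed "
                      f"bivalent genes have positive net intensity; "
                      f"{100 * row['f_silent_given_net_nonpositive']:.0f}% of "
                      f"net-non-positive genes are silent")

    # recovery against the planted truth
    truth = pd.read_csv(args.sim / "truth.tsv", sep="\t")
    rec_rows = []
    for cond, cls_col in ((cond1, "class_1"), (cond2, "class_2")):
        recovered = analyses[cond].class_by_symbol()
        truth[f"recovered_{cls_col}"] = truth["symbol"].map(recovered)
        acc = (truth[f"recovered_{cls_col}"] == truth[cls_col]).mean()
        rec_rows.append({"condition": cond, "class_accuracy": acc})
        print(f"{cond}: planted mark-class recovery {100 * acc:.1f}%")
    contrast = contrast_conditions(analyses[cond1], analyses[cond2],
                                   inputs.expression[cond1], inputs.expression[cond2])
    detected = {(q.symbol, mark): q.quadrant
                for mark, quads in contrast.quadrants.items() for q in quads}
    n_planted = n_found = 0
    for col, mark in (("quadrant_K4", "H3K4me3"), ("quadrant_K27", "H3K27me3")):
        planted = truth[truth[col] != "."]
        n_planted += len(planted)
        n_found += sum(detected.get((s, mark)) == q
                       for s, q in zip(planted["symbol"], planted[col]))
    sens = n_found / n_planted if n_planted else float("nan")
    print(f"planted concordance quadrants: {n_found}/{n_planted} recovered "
          f"({100 * sens:.1f}% sensitivity)")
    pd.DataFrame(rec_rows + [{"condition": "both", "quadrant_sensitivity": sens}]).to_csv(
        args.out / "recovery.tsv", sep="\t", index=False, float_format="%.4f")


if __name__ == "__main__":
    main()
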