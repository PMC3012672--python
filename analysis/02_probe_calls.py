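"""Per-probe significance and neighborhood bound calls for every track.

Reads the simulated experiment from results/sim/, fits a robust Gaussian
null per track, and writes one call table per (mark, condition) plus a
per-track summary (significant and bound fractions) under results/.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from epibalance import estimate_null, neighborhood_bound_call
from epibalance.pipeline import load_experiment


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--sim", type=Path, default=Path("results/sim"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    inputs = load_experiment(args.sim)
    args.out.mkdir(parents=True, exist_ok=True)
    summary_rows = []
    for (mark, cond), track in sorted(inputs.tracks.items()):
        null = estimate_null(track)
        calls = neighborhood_bound_call(track, inputs.probes, null)
        df = pd.DataFrame(
            {
                "probe_id": [c.probe_id for c in calls],
                "log2ratio": [c.log2ratio for c in calls],
                "p_x": [c.p_x for c in calls],
                "xbar": [c.xbar for c in calls],
                "p_xbar": [c.p_xbar for c in calls],
                "significant": [int(c.significant) for c in calls],
                "bound": [int(c.bound) for c in calls],
            }
        )
        df.to_csv(args.out / f"probe_calls_{mark}_{cond}.tsv", sep="\t",
                  index=False, float_format="%.6g")
        summary_rows.append(
            {
                "mark": mark,
                "condition": cond,
                "null_mu": null.mu,
                "null_sigma": null.sigma,
                "f_significant": df["significant"].mean(),
                "f_bound": df["bound"].mean(),
            }
        )
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(args.out / "probe_call_summary.tsv", sep="\t", index=False,
                   float_format="%.6g")
    print(summary.to_string(index=False))
    print("histone tracks carry more significant probes than DNAMe, as planted"
          if summary.set_index("mark")["f_significant"].groupby(level=0).mean()["DNAMe"]
          < summary.set_index("mark")["f_significant"].groupby(level=0).mean()["H3K4me3"]
          else "warning: DNAMe significant fraction unexpectedly high")


if __name__ == "__main__":
    main()
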