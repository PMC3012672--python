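# epibalance

Integrative analysis of promoter histone methylation (H3K4me3, H3K27me3),
DNA methylation (DNAMe) and gene expression on promoter tiling arrays, for
contrasts between two cell states such as an epithelial-to-mesenchymal
transition (EMT).

The package is aimed at epigenomics analysts working with ChIP-chip /
MeDIP-chip promoter arrays (probe-level log2 IP/control ratios tiled over
windows from 5.5 kb upstream to 2.5 kb downstream of each TSS) together with
matched expression arrays. Its central idea is *quantitative balance*: for a
gene carrying both an activating and a repressive mark, transcription tracks
the **net intensity**

```
net(g) = T_H3K4me3(g) − T_repressive(g),      T_m(g) = Σ_p max(x_mp, 0)
```

where `x_mp` is the log2 ratio of probe `p` of mark `m` assigned to gene
`g`'s scoring region, and the repressive mark is H3K27me3 or DNAMe. Genes
with `T_m > 7` are *marked*, probes with `x > 1` are *significant*, genes
with log2 expression `> 7.5` are *active*, and between-condition changes are
differential when `|Δ T_m| > 5` (marks) or `|Δ log2 expr| > 2` (expression).

## What it computes

* **arraydata** — tab-delimited track / BED annotation / expression I/O,
  strand-oriented promoter windows, interval-overlap probe-to-gene mapping,
  and the common gene universe of the two platforms.
* **probecall** — probe significance, a robust Gaussian null (median/MAD),
  and the neighborhood "bound" call: a probe is bound iff P(X̄) < 0.001 over
  its ≤1000 bp neighborhood, its own P(X) < 0.001, and at least one neighbor
  has P(X) < 0.1.
* **genescore** — gene-level totals, marked-gene sets, the eight
  mark-combination classes, net intensity and its group aggregates.
* **bivalency** — bivalent probes (significant in both marks of a pair),
  clustered (≥3 probes per gene) vs sporadic co-modification, trivalent
  sites.
* **differential** — mark and expression deltas, concordance quadrants
  (H3K4me3 moving with expression, H3K27me3 against it), top-N changed
  genes.
* **assoc_stats** — active/silent classification, group medians and
  fractions expressed, net-sign conditional fractions, Pearson chi-square
  association tests.
* **synthdata** — a seeded generator of complete two-condition experiments
  with planted ground truth (classes, islands, net intensities, switch
  quadrants), so the whole pipeline is testable without any download.

## Worked example

The `analysis/` scripts run the pipeline end to end on a simulated
experiment (2000 genes, two conditions, 10% of genes switching mark class):

```
$ python analysis/01_simulate.py --seed 1
simulated 2000 genes, 86100 probes (4100 intergenic decoys), seed 1
...
$ python analysis/03_gene_scores.py
2000 genes in the common universe; 4100 probes unmapped (intergenic)
epithelial: 1138 genes marked by H3K4me3
epithelial: 540 genes marked by H3K27me3
epithelial: 590 genes marked by DNAMe
epithelial K4_vs_K27: n=313 bivalent genes, sum positive 6142, sum negative -6024
...
$ python analysis/06_association.py
epithelial: 87% of H3K4me3-marked genes expressed (chi2=720, p=1.5e-158); DNAMe-marked 56% expressed
epithelial K4_vs_K27: 85% of expressed bivalent genes have positive net intensity; 83% of net-non-positive genes are silent
...
epithelial: planted mark-class recovery 99.5%
planted concordance quadrants: 136/143 recovered (95.1% sensitivity)
```

Reading the output: the activating mark dominates coverage (~57% of genes),
is strongly associated with activity (chi-square on the 2×2 mark × activity
table), and within the bivalent H3K4/K27 group the *sign of the net
intensity* — not the mere presence of the repressive mark — separates
expressed from silent genes. Because the inputs are simulated, the last
lines score the pipeline against the planted truth: 99.5% of mark classes
and 95% of planted concordance quadrants are recovered.

Scripts `02_probe_calls.py`, `04_bivalency.py` and `05_differential.py`
cover the remaining stages (bound calls per track, clustered vs sporadic
co-modification, differential counts and top-100 changed genes); all tables
land under `results/`.

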