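# Methods

## The analysis model

The pipeline treats promoter epigenetics quantitatively rather than as
binary presence/absence. Inputs are probe-level normalized log2 IP/control
ratios from promoter tiling arrays (one track per mark and condition), a
gene annotation, and per-condition log2 expression tables clipped to
[5, 16]. All coordinates are 0-based half-open.

**Windows and scoring regions.** Each gene's promoter window runs from
5.5 kb upstream to 2.5 kb downstream of the TSS, strand-oriented (8 kb
total). The scoring region is the union of the window and the annotated
gene span; since both contain the TSS this is a single interval, and probes
in the gene body beyond the downstream window edge still count toward the
gene. Probes are assigned to genes by interval overlap with the scoring
region; a probe may serve several genes, and unassigned probes are counted
but otherwise ignored.

**Probe calls.** A probe is *significant* when its ratio is strictly above
1. The *bound* call follows the per-array neighborhood family of tiling
models: probes whose midpoints lie within 1000 bp are neighbors; the
central ratio X and the unweighted neighborhood mean X̄ are referred to a
Gaussian null, and a probe is bound iff P(X̄) < 0.001, P(X) < 0.001, and at
least one neighbor has P(X) < 0.1. Probes without neighbors are never
bound. The internal weighting of the original commercial implementation is
unpublished, so the neighborhood mean is unweighted and P(X̄) is computed
against Normal(μ, σ/√k) with k the number of averaged probes — a
parameter-compatible model, documented as this package's own choice. The
null (μ, σ) is estimated robustly as the median and 1.4826 × MAD, because
enriched probes inflate naive moments; a zero MAD is a degenerate track and
an error.

**Gene scores and classes.** The total intensity of a (gene, mark,
condition) is the sum of assigned probe ratios with negatives clipped to
zero; missing probes are excluded, never imputed. Genes with total strictly
above 7 are *marked*. Thresholds are strict everywhere ("above" excludes
ties): probe > 1, total > 7, expression > 7.5, |Δ| > 5 / > 2. Per
condition, genes partition into the eight mark combinations. Group
vocabulary used in reports: "bivalent H3K4/K27" and "bivalent H3K4/DNAMe"
include trivalent genes (both members marked, third mark free); "DNAMe
without H3K4me3" is DNAMe_only ∪ K27_DNAMe, with the strict DNAMe_only
class exposed separately.

**Net intensity.** For a bivalent gene the activating total enters with
positive sign and the repressive total with negative sign; net = positive +
negative. A net of exactly 0 falls on the non-positive side, and an
expression value of exactly 7.5 counts as silent — the source definitions
are strict on both sides, so ties need an assignment, and both ties go to
the non-active side. Conditional fractions are reported in both directions
(conditioning on activity and on net sign) with explicit denominators; an
empty denominator yields an undefined (None) fraction, not 0.

**Differential analysis.** Mark deltas are computed on gene-level totals
(consistent with the marked-gene definition), expression deltas on the
clipped log2 values; |Δ| strictly above the threshold with the sign giving
direction. Concordance quadrants join one mark's differential call with the
expression call per gene: H3K4me3 concordance is same-direction, H3K27me3
concordance opposite-direction, mismatches are discordant; genes may appear
in both marks' joins. Top-N ranking is by |Δ| descending with lexicographic
tie-break on the symbol.

**Association tests.** Mark-vs-activity association uses Pearson's
chi-square on the 2×2 table without continuity correction, p-values from
the χ²(1 df) distribution. Zero margins are an error rather than a 0/0
fraction. Group medians are reported descriptively alongside.

## The synthetic-data generator

The generator emulates the features of promoter-array data that the
analysis relies on, with planted ground truth for exact scoring.

* **Layout.** Genes sit on a 25 kb grid (windows can never overlap), 500
  per synthetic chromosome, random strand, gene length uniform 2–10 kb.
  Each window is tiled by 41 probes at 200 bp spacing, each probe a 60-mer
  centered on its tile position so the endpoint probes overlap the
  half-open window. 5% decoy probes are placed in guaranteed-intergenic
  gaps to exercise unmapped-probe reporting.
* **Classes and islands.** Each gene draws one of the eight classes
  (defaults: none .25, K4_only .30, K27_only .08, DNAMe_only .07, K4_K27
  .10, K4_DNAMe .12, K27_DNAMe .03, trivalent .05 — giving mark coverage
  around 57% / 26% / 27%, the structure seen on real promoter arrays where
  the activating mark dominates). Histone marks plant one contiguous island
  of 6–12 probes at per-probe mean 1.8; DNAMe plants exactly 2 sporadic
  probes at mean 5.0. These means and lengths are chosen so planted marked
  totals (≥10.8 histone, 10 DNAMe) clear the marked threshold 7 with a
  margin of about 3 units while DNAMe stays sporadic with few significant
  probes per gene. Background probes are N(0, 0.25); at this σ the clipped
  background sum over 41 probes is ≈4.1 ± 0.9, keeping false marked genes
  at the per-mille level. (A background σ of 0.35 would push the clipped
  background sum over the threshold for ~16% of unmarked genes, destroying
  the marked/unmarked separation the threshold implies, which is why 0.25
  is the default.)
* **Expression link.** log2 expression = clip(β₀ + β_net·(T_K4 − T_K27) +
  β_DNAMe·T_DNAMe·1[K4 absent] + ε, 5, 16) with β₀ = 7.5, β_net = 0.35,
  β_DNAMe = −0.15, ε ~ N(0, 0.8). This is the simplest monotone link
  consistent with the net-intensity/activity relationship the analysis
  tests — an assumption of the generator, not a result. Unmarked genes
  center at β₀; because activating marks outnumber repressive ones, the
  population median sits about one unit above β₀.
* **EMT switch.** A configurable fraction of genes (default 10%) re-draw
  their class from a kernel biased toward K4 gain and DNAMe loss (redraw
  masses: K4-bearing classes 0.76, K27 0.37, DNAMe 0.17), re-plant their
  islands, and regenerate expression; non-switching genes keep their island
  plans so their deltas are pure noise. Planted concordance quadrants are
  derived from the planted deltas (mark totals and clipped expression
  means) under the same strict thresholds the analysis uses.
* **Determinism.** All randomness flows from one `SeedSequence` spawned
  into independent streams per stage; emitted files use fixed 6-decimal
  formatting, so a fixed seed yields byte-identical output.

**What the generator does not emulate.** No raw two-color intensities, dye
bias, spatial artifacts, probe GC/affinity effects, CpG-island structure,
replicate variability, or correlated noise along the genome. Background
noise is iid Gaussian and islands have a single flat mean, so the planted
recovery rates (≈99.5% classes, ≈93–95% quadrants) are an upper bound on
what identically-thresholded analysis would achieve on real arrays; passing
recovery tests validates the pipeline's logic, not the thresholds'
real-data operating characteristics.

## Numerical choices and degenerate inputs

* Duplicate symbols in expression input keep the maximum value (a gene is
  expressed if any probe says so); duplicate probe ids are an error.
* Missing probe values are excluded from sums, significance counts and
  neighborhoods.
* Tie handling: every threshold is strict; exactly-threshold values fall on
  the unmarked / silent / unchanged / non-positive side.
* `estimate_null` requires ≥100 probes and a non-zero MAD; probe inputs to
  the neighborhood model must be start-sorted within chromosomes (checked,
  not silently re-sorted).
* Empty gene groups, empty universes and zero contingency margins raise
  instead of returning 0s, since each signals an upstream mismatch.
* Default problem sizes: unit and property tests run at a few hundred genes;
  end-to-end recovery uses 2000 genes × 5 seeds and null calibration uses
  10 tracks of 10,000 probes, sizes at which the binomial error of the
  measured rates is well inside the asserted margins.

## Known limitations

* The marked-gene threshold 7 is a sum of per-probe log2 ratios and is
  therefore array-density dependent; it is exposed as a parameter but no
  portability correction is attempted.
* Gene matching is by symbol, case-sensitive; no identifier mapping.
* The bound-call model is a documented stand-in for an unpublished vendor
  model: parameters match, internal weighting may not.
* No replicate merging, probe-level FDR, GO enrichment, normalization of
  raw intensities, or genome liftover.
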