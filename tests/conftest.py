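from __future__ import annotations

import numpy as np
import pytest

from epibalance import GeneModel, MarkTrack, ProbeRecord, SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_sim():
    """A modest two-condition simulation shared by read-only tests."""
    return simulate_experiment(SimConfig(n_genes=200, seed=11))


def random_instance(rng: np.random.Generator, n_genes: int, n_probes: int):
    """A random probe/gene layout for oracle-equivalence checks.

    Genes are packed densely enough that probes frequently overlap several
    scoring regions, exercising multi-gene assignment.
    """
    genes = []
    for i in range(n_genes):
        chrom = f"chr{rng.integers(1, 4)}"
        tss = int(rng.integers(10_000, 120_000))
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(1_000, 12_000))
        gene_end = tss + length if strand == "+" else tss - length
        genes.append(GeneModel(f"G{i:04d}", chrom, strand, tss, gene_end))
    probes = []
    for j in range(n_probes):
        chrom = f"chr{rng.integers(1, 4)}"
        start = int(rng.integers(0, 140_000))
        probes.append(ProbeRecord(f"p{j:05d}", chrom, start, start + 60))
    return genes, probes


def random_track(rng: np.random.Generator, probes, mark="H3K4me3", condition="c1",
                 loc=0.5, scale=1.0):
    values = {p.probe_id: float(v) for p, v in
              zip(probes, rng.normal(loc, scale, len(probes)))}
    return MarkTrack(mark=mark, condition=condition, values=values)
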