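"""Shared fixtures: a hand-built toy gene and a small simulated bundle."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import mecirc as mc
from mecirc._seq import revcomp

BASES = "ACGT"


def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def build_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    exon_seqs: list[str],
    intron_seqs: list[str],
    pad: str = "T" * 30,
) -> tuple[dict[str, str], mc.GeneModel]:
    """Assemble a single-gene contig from transcript-oriented pieces."""
    assert len(intron_seqs) == len(exon_seqs) - 1
    parts, offsets, pos = [pad], [], len(pad)
    for i, eseq in enumerate(exon_seqs):
        offsets.append(pos)
        parts.append(eseq)
        pos += len(eseq)
        if i < len(intron_seqs):
            parts.append(intron_seqs[i])
            pos += len(intron_seqs[i])
    parts.append(pad)
    total = "".join(parts)
    T = len(total)
    genome = {chrom: total if strand == "+" else revcomp(total)}
    recs = []
    for i, eseq in enumerate(exon_seqs):
        if strand == "+":
            s, e = offsets[i], offsets[i] + len(eseq)
        else:
            s, e = T - (offsets[i] + len(eseq)), T - offsets[i]
        recs.append(mc.ExonRecord(gene_id, i + 1, chrom, s, e, strand, eseq))
    return genome, mc.GeneModel(gene_id, chrom, strand, recs)


@dataclass
class ToyGene:
    genome: dict[str, str]
    models: dict[str, mc.GeneModel]
    index: mc.ExonIndex
    exon_seqs: list[str]


@pytest.fixture(scope="session")
def toy_gene() -> ToyGene:
    """One + strand gene, three 40-nt exons, GT..AG introns, k=8 index."""
    rng = np.random.default_rng(42)
    exons = [rand_seq(rng, 40) for _ in range(3)]
    introns = ["GT" + rand_seq(rng, 60) + "AG" for _ in range(2)]
    genome, model = build_gene("G", "chrT", "+", exons, introns)
    models = {"G": model}
    return ToyGene(genome, models, mc.build_exon_index(models, k=8), exons)


@dataclass
class SimBundle:
    config: mc.SimConfig
    genome: dict[str, str]
    models: dict[str, mc.GeneModel]
    truth: mc.SimTruth
    reads: list[tuple[str, str]]
    index: mc.ExonIndex


def make_bundle(config: mc.SimConfig, k: int = 12) -> SimBundle:
    genome, models, truth = mc.make_genome(config)
    reads, truth = mc.simulate_reads(models, truth, config)
    return SimBundle(config, genome, models, truth, reads, mc.build_exon_index(models, k))


@pytest.fixture(scope="session")
def sim_bundle() -> SimBundle:
    """Small error-free library: 8 genes, 6 circRNAs (3 with inserts)."""
    return make_bundle(
        mc.SimConfig(
            n_genes=8,
            n_circ=6,
            fraction_me=0.5,
            me_len=(6, 30),
            linear_read_fraction=0.1,
            seed=11,
        )
    )
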