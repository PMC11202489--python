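#!/usr/bin/env python
"""Generate every input of the study's computational chain, with truth.

Writes under results/run: a toy genome (FASTA + GTF) carrying 30 planted
GT/AG-flanked circRNA junctions with 3 unique spanning reads each
(FASTQ per sample), miRNA/circRNA/mRNA count matrices with 15 planted ceRNA
triples among 200 decoys, a miRNA count matrix planting the 24 printed
fold-change rows, and the truth tables the later steps are scored against.
"""

import sys
from pathlib import Path

import numpy as np

from shellnet import io, synthetic
from shellnet.containers import PlantedTruth
from shellnet.design import make_design
from shellnet.pipeline import _stage_seeds

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
OUT = Path("results/run")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(SEED)
    design = make_design()  # 13 shell-gland samples: DB1..3, LB1..3, DP1..4, PK1..3

    genome, reads, jx_truth = synthetic.simulate_genome_and_reads(
        n_genes=30, n_circ=30, read_length=100, junction_depth=3,
        n_linear=1000, design=design, seed=seeds[0])
    io.write_fasta(genome.sequences, OUT / "genome.fa")
    io.write_gtf(genome, OUT / "annotation.gtf")
    io.write_fastq_per_sample(reads, OUT / "reads")

    cerna_truth = synthetic.make_cerna_truth(n_triples=15, n_decoys=200,
                                             seed=seeds[1])
    expr = synthetic.simulate_cerna_expression(design, cerna_truth,
                                               coupling=0.9, noise_sd=0.2,
                                               seed=seeds[2])
    for klass, cm in expr.items():
        io.write_counts(cm, OUT / f"counts_{klass}.tsv")

    de_counts, expected = synthetic.table2_fixture(seed=seeds[3])
    io.write_counts(de_counts, OUT / "counts_mirna_de.tsv")
    expected.to_csv(OUT / "de_expected.tsv", sep="\t", index=False)

    truth = PlantedTruth(de_features=synthetic.table2_truth().de_features,
                         junctions=jx_truth.junctions,
                         target_edges=cerna_truth.target_edges,
                         cerna_triples=cerna_truth.cerna_triples)
    io.write_truth(truth, OUT / "truth")

    genome_kb = len(genome.sequences["chr1"]) / 1000
    print(f"seed {SEED}: genome {genome_kb:.1f} kb, {len(reads.reads)} reads, "
          f"{len(jx_truth.junctions)} planted junctions, "
          f"{len(cerna_truth.cerna_triples)} planted ceRNA triples, "
          f"{sum(len(v) for v in cerna_truth.target_edges.values())} target edges")


if __name__ == "__main__":
    main()
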