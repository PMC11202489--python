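#!/usr/bin/env python
"""Expression metrics for each RNA class, plus a worked 2^-ddCt example.

miRNA counts -> tags-per-million (length-homogeneous small RNAs); mRNA
counts -> FPKM with simulated transcript lengths; circRNA junction support
-> RPM. Also evaluates the relative-expression statistic on a small
synthetic Ct table, as qPCR validation would.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from shellnet import io, quantify
from shellnet.containers import CountMatrix

RUN = Path("results/run")


def main() -> None:
    mirna = io.read_counts(RUN / "counts_mirna.tsv")
    tpm = quantify.tpm(mirna)
    tpm.to_csv(RUN / "tpm_mirna.tsv", sep="\t")

    mrna = io.read_counts(RUN / "counts_mrna.tsv")
    rng = np.random.default_rng(0)  # transcript lengths are fixture metadata
    lengths = pd.Series(rng.integers(500, 3000, size=len(mrna.counts)),
                        index=mrna.counts.index, name="length")
    fpkm = quantify.fpkm(CountMatrix(counts=mrna.counts, lengths=lengths))
    fpkm.to_csv(RUN / "fpkm_mrna.tsv", sep="\t")

    circ = io.read_counts(RUN / "counts_circ.tsv")
    cpm = quantify.tpm(circ)
    cpm.to_csv(RUN / "rpm_circ.tsv", sep="\t")

    ct = pd.DataFrame([
        {"gene": "miR-2995-x", "condition": "experimental", "ct": 21.3},
        {"gene": "U6", "condition": "experimental", "ct": 17.1},
        {"gene": "miR-2995-x", "condition": "control", "ct": 24.8},
        {"gene": "U6", "condition": "control", "ct": 17.0},
    ])
    fold = quantify.delta_delta_ct(ct, target="miR-2995-x", reference="U6")

    print(f"TPM columns sum to {tpm.sum(axis=0).iloc[0]:,.0f} "
          f"(conservation check)")
    print(f"FPKM matrix {fpkm.shape[0]} features x {fpkm.shape[1]} samples, "
          f"median {np.median(fpkm.to_numpy()):,.0f}")
    print(f"worked 2^-ddCt example: ddCt = (21.3-17.1)-(24.8-17.0) = -3.6 "
          f"-> fold change {fold:.2f}")


if __name__ == "__main__":
    main()
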