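"""Expression metrics (TPM, FPKM, RPM) and the RT-qPCR 2^-ddCt statistic.

A deliberate simplification, stated prominently: the miRNA "TPM" here is
counts-per-million with no length term. Small-RNA tags are essentially
length-homogeneous (~22 nt), so the per-kilobase normalisation cancels and
the field's small-RNA pipelines quantify in reads-per-million anyway.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix


def tpm(cm: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Tags per million for length-homogeneous small-RNA counts.

    Per sample: count * 1e6 / column total. Columns sum to 1e6 exactly
    (up to float round-off). Raises on an all-zero sample.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"sample(s) with zero total counts: {bad}")
    return counts * 1e6 / totals


def fpkm(cm: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    count * 1e9 / (length_nt * column total). The library size is the
    column total of the analysed matrix; no external mapped-read figure
    is consulted.
    """
    if cm.lengths is None:
        raise ValueError("FPKM requires feature lengths")
    lengths = cm.lengths.astype(float)
    if lengths.isna().any() or (lengths <= 0).any():
        bad = list(lengths.index[lengths.isna() | (lengths <= 0)])
        raise ValueError(f"missing/non-positive lengths for: {bad[:5]}")
    totals = cm.counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("sample with zero total counts")
    return cm.counts.mul(1e9, axis=0).div(lengths, axis=0).div(totals, axis=1)


def rpm(support: pd.DataFrame, mapped_totals: pd.Series) -> pd.DataFrame:
    """Back-spliced reads per million mapped reads.

    ``support`` holds per-sample unique back-splice-junction read counts;
    ``mapped_totals`` the per-sample mapped read totals. RPM = support *
    1e6 / mapped_total.
    """
    mapped_totals = mapped_totals.reindex(support.columns).astype(float)
    if mapped_totals.isna().any() or (mapped_totals <= 0).any():
        raise ValueError("mapped totals must be present and positive for every sample")
    return support * 1e6 / mapped_totals


def delta_delta_ct(ct: pd.DataFrame, target: str, reference: str = "GAPDH") -> float:
    """Relative expression by the 2^-ddCt method.

    ``ct`` is a long-format table with columns (sample, gene, role,
    condition, ct); roles are {target, reference} and conditions
    {experimental, control}. Replicate Ct values are averaged per
    (gene, condition) before differencing.

    ddCt = (Ct_target,exp - Ct_ref,exp) - (Ct_target,ctl - Ct_ref,ctl)
    and the returned fold change is 2^-ddCt. The reference gene is a
    parameter (GAPDH for mRNA, U6 for miRNA/circRNA by convention).
    """
    required = {"gene", "condition", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")

    def mean_ct(gene: str, condition: str) -> float:
        rows = ct[(ct["gene"] == gene) & (ct["condition"] == condition)]
        if rows.empty:
            raise ValueError(f"missing Ct for gene={gene!r}, condition={condition!r}")
        return float(rows["ct"].mean())

    ddct = ((mean_ct(target, "experimental") - mean_ct(reference, "experimental"))
            - (mean_ct(target, "control") - mean_ct(reference, "control")))
    return float(2.0 ** (-ddct))


def read_ct_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    tab.columns = [c.strip().lower() for c in tab.columns]
    return tab
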