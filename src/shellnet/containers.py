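"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StudyDesign


@dataclass
class CountMatrix:
    """Integer read counts, features x samples, with the design attached.

    ``counts`` is a pandas DataFrame indexed by feature id with one column
    per sample. ``lengths`` (nt) is only needed for FPKM.
    """

    counts: pd.DataFrame
    design: StudyDesign | None = None
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.design is not None:
            missing = set(self.counts.columns) - set(self.design.samples)
            if missing:
                raise ValueError(f"samples not in design: {sorted(missing)}")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def group_columns(self, group: str) -> pd.DataFrame:
        if self.design is None:
            raise ValueError("no design attached")
        cols = [s for s in self.design.samples_by_group[group]
                if s in self.counts.columns]
        return self.counts[cols]


@dataclass
class Gene:
    """A gene with its exon structure, 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]


@dataclass
class ToyGenome:
    """Chromosome sequences plus gene/exon annotation."""

    sequences: dict[str, str]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            L = len(self.sequences[g.chrom])
            for s, e in g.exons:
                if not (0 <= s < e <= L):
                    raise ValueError(
                        f"gene {g.gene_id}: exon ({s},{e}) outside {g.chrom} (len {L})")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]


@dataclass
class Read:
    read_id: str
    sample: str
    sequence: str


@dataclass
class ReadSet:
    """Single-end reads tagged with their sample of origin."""

    reads: list[Read]
    read_length: int

    def __post_init__(self) -> None:
        for r in self.reads:
            if set(r.sequence) - set("ACGT"):
                raise ValueError(f"read {r.read_id}: non-ACGT characters")

    def by_sample(self) -> dict[str, list[Read]]:
        out: dict[str, list[Read]] = {}
        for r in self.reads:
            out.setdefault(r.sample, []).append(r)
        return out


@dataclass
class PlantedTruth:
    """Ground truth planted by the synthetic generators.

    de_features: feature id -> (comparison label, signed log2FC)
    junctions:   list of (chrom, start, end, strand) genomic spans
    target_edges: miRNA id -> set of RNA ids it targets
    cerna_triples: list of (circ id, miRNA id, mRNA id)
    """

    de_features: dict[str, tuple[str, float]] = field(default_factory=dict)
    junctions: list[tuple[str, int, int, str]] = field(default_factory=list)
    target_edges: dict[str, set[str]] = field(default_factory=dict)
    cerna_triples: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for circ, mir, mrna in self.cerna_triples:
            targets = self.target_edges.get(mir, set())
            if circ not in targets or mrna not in targets:
                raise ValueError(
                    f"triple ({circ},{mir},{mrna}): miRNA must target both partners")


def counts_to_frame(cm: CountMatrix) -> pd.DataFrame:
    out = cm.counts.copy()
    out.index.name = "feature"
    return out


def assert_integer_counts(df: pd.DataFrame) -> pd.DataFrame:
    arr = df.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("count matrix must contain integers")
    return df.astype(np.int64)
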