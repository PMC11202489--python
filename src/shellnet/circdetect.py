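"""Back-splice junction calling from reads against a toy reference.

The procedure follows the classic anchor strategy for circRNA discovery:
take a 20-mer from each end of a read, map both exactly to the genome, and
look for "head-to-tail" configurations in which the read's left anchor lands
*downstream* of its right anchor — the signature of a covalently closed
circle. The two anchor alignments are then extended toward each other until
the entire read is explained by two genomic segments meeting at a single
breakpoint pair, and the breakpoints must carry the canonical splice
dinucleotides (GT after the donor, AG before the acceptor, on the candidate
strand). Candidates need at least two unique spanning reads in at least one
sample to survive.

Anchor mapping is exact (a hash of every genomic k-mer on both strands):
alignment proper is a solved problem delegated to external mappers on real
data, and exact matching keeps the calling logic fully verifiable on toy
genomes. A read is used only if exactly one breakpoint pair survives
extension plus splice-site validation; ambiguous reads are discarded and
counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .containers import Gene, ReadSet, ToyGenome
from .synthetic import revcomp

log = logging.getLogger(__name__)

ANCHOR_LEN = 20

# splice flank dinucleotides around a genomic span [start, end):
# '+' circles read AG | acceptor ... donor | GT on the forward strand;
# '-' circles carry the reverse complement (AC ... CT in forward coordinates)
_FLANK_RULES = {"+": ("AG", "GT"), "-": ("AC", "CT")}


@dataclass(frozen=True)
class AnchorPair:
    read_id: str
    left: str
    right: str
    sequence: str


@dataclass
class BackspliceCandidate:
    """A called circRNA junction: genomic span [start, end) plus support.

    ``start`` is the upstream breakpoint and ``end`` the downstream one in
    genome coordinates; for '+' candidates start is the acceptor and end the
    donor, for '-' candidates the biological roles are swapped.
    """

    chrom: str
    start: int
    end: int
    strand: str
    support: dict[str, int] = field(default_factory=dict)
    annotation: str | None = None

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @property
    def max_support(self) -> int:
        return max(self.support.values(), default=0)


def extract_anchors(read_id: str, sequence: str, k: int = ANCHOR_LEN) -> AnchorPair:
    """First and last k-mers of a read; requires length >= 2k."""
    if len(sequence) < 2 * k:
        raise ValueError(
            f"read {read_id}: length {len(sequence)} < 2 x anchor length {k}")
    return AnchorPair(read_id=read_id, left=sequence[:k], right=sequence[-k:],
                      sequence=sequence)


class KmerIndex:
    """Exact-match index of all genomic k-mers, both strands."""

    def __init__(self, genome: ToyGenome, k: int = ANCHOR_LEN):
        self.k = k
        self.genome = genome
        self._index: dict[str, list[tuple[str, int, str]]] = {}
        for chrom, seq in genome.sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                self._index.setdefault(kmer, []).append((chrom, i, "+"))
        # minus-strand hits are reported at their forward-coordinate position
        for chrom, seq in genome.sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = revcomp(seq[i:i + k])
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((chrom, i, "-"))

    def map_anchor(self, anchor: str) -> list[tuple[str, int, str]]:
        """All exact occurrences of the anchor (fwd and revcomp), with strand."""
        bad = set(anchor) - set("ACGT")
        if bad:
            raise ValueError(f"anchor contains non-ACGT characters: {sorted(bad)}")
        return list(self._index.get(anchor, []))

    def forward_hits(self, anchor: str) -> list[tuple[str, int]]:
        return [(c, p) for c, p, s in self.map_anchor(anchor) if s == "+"]


def _flanks_ok(seq: str, start: int, end: int, strand: str) -> bool:
    before, after = _FLANK_RULES[strand]
    if start < 2 or end + 2 > len(seq):
        return False
    return seq[start - 2:start] == before and seq[end:end + 2] == after


def _spans_for_orientation(read: str, index: KmerIndex, k: int,
                           require_flanks: bool = True
                           ) -> set[tuple[str, int, int, str]]:
    """Head-to-tail spans explaining ``read`` as two forward-genome segments.

    The oriented read must equal genome[end-j : end] + genome[start : start+m]
    for some breakpoint split j + m = len(read), with the left segment
    genomically downstream of the right one. The strand is then assigned by
    which splice-flank rule the span satisfies.
    """
    n = len(read)
    left_hits = index.forward_hits(read[:k])
    right_hits = index.forward_hits(read[-k:])
    spans: set[tuple[str, int, int, str]] = set()
    for lc, pl in left_hits:
        seq = index.genome.sequences[lc]
        for rc, pr in right_hits:
            if rc != lc or pl <= pr:  # head-to-tail: left anchor downstream
                continue
            for j in range(k, n - k + 1):
                end = pl + j                      # donor-side breakpoint (excl)
                start = pr + k - (n - j)          # acceptor-side breakpoint
                if start < 0 or end > len(seq) or start >= end:
                    continue
                if seq[pl:end] != read[:j]:
                    break  # left extension failed; longer j cannot match
                if seq[start:start + (n - j)] != read[j:]:
                    continue
                flanked = [s for s in ("+", "-") if _flanks_ok(seq, start, end, s)]
                for strand in flanked:
                    spans.add((lc, start, end, strand))
                if not flanked and not require_flanks:
                    spans.add((lc, start, end, "."))
    return spans


def call_backsplice(read_id: str, sequence: str, index: KmerIndex,
                    k: int = ANCHOR_LEN,
                    counters: dict[str, int] | None = None,
                    require_flanks: bool = True) -> BackspliceCandidate | None:
    """Call a single back-splice junction from one read, or None.

    Both the read and its reverse complement are examined, so calling is
    orientation-invariant. If more than one distinct (span, strand) survives
    extension + splice-flank validation the read is ambiguous and rejected
    (counted in ``counters['ambiguous']`` when a counter dict is supplied).
    ``require_flanks=False`` disables the splice-site check (diagnostic use
    only; unflanked spans get strand '.').
    """
    if len(sequence) < 2 * k:
        raise ValueError(f"read {read_id}: shorter than 2 x anchor length")
    spans: set[tuple[str, int, int, str]] = set()
    for oriented in (sequence, revcomp(sequence)):
        spans |= _spans_for_orientation(oriented, index, k, require_flanks)
    if not spans:
        return None
    if len(spans) > 1:
        if counters is not None:
            counters["ambiguous"] = counters.get("ambiguous", 0) + 1
        log.debug("read %s: %d consistent breakpoint pairs, rejected",
                  read_id, len(spans))
        return None
    chrom, start, end, strand = next(iter(spans))
    return BackspliceCandidate(chrom=chrom, start=start, end=end, strand=strand)


def detect_backsplices(reads: ReadSet, genome: ToyGenome, k: int = ANCHOR_LEN,
                       ) -> tuple[list[BackspliceCandidate], dict[str, int]]:
    """Run the caller over a read set and tally per-sample unique support.

    A supporting read is "unique" as a (sequence, breakpoint) pair: exact
    duplicate reads for the same junction in the same sample collapse to one.
    Returns unfiltered candidates plus run counters.
    """
    index = KmerIndex(genome, k)
    counters: dict[str, int] = {"reads": 0, "ambiguous": 0, "called": 0}
    seen: dict[str, BackspliceCandidate] = {}
    unique_reads: dict[str, set[tuple[str, str]]] = {}  # key -> {(sample, seq)}
    for read in reads.reads:
        counters["reads"] += 1
        cand = call_backsplice(read.read_id, read.sequence, index, k, counters)
        if cand is None:
            continue
        counters["called"] += 1
        cur = seen.setdefault(cand.key, cand)
        pairs = unique_reads.setdefault(cand.key, set())
        pairs.add((read.sample, read.sequence))
    for key, cand in seen.items():
        support: dict[str, int] = {}
        for sample, _seq in unique_reads[key]:
            support[sample] = support.get(sample, 0) + 1
        cand.support = support
    out = sorted(seen.values(), key=lambda c: (c.chrom, c.start, c.end))
    return out, counters


def filter_candidates(candidates: list[BackspliceCandidate],
                      min_unique: int = 2) -> list[BackspliceCandidate]:
    """Keep candidates with >= min_unique unique reads in at least one sample."""
    return [c for c in candidates if c.max_support >= min_unique]


def _overlapping_genes(cand: BackspliceCandidate, genes: list[Gene]) -> list[Gene]:
    return [g for g in genes
            if g.chrom == cand.chrom and g.start < cand.end and cand.start < g.end]


def annotate_circ(cand: BackspliceCandidate, genes: list[Gene]) -> str:
    """Assign exactly one genomic-context class to a candidate.

    Priority within a same-strand overlapping gene: wholly inside one exon
    -> one_exon; both breakpoints on exon boundaries spanning >= 2 exons ->
    annot_exons; wholly inside one intron -> intronic; any other mix of exon
    and intron sequence -> exon_intron. With only opposite-strand gene
    overlap -> antisense; with no gene overlap -> intergenic.
    """
    overlapping = _overlapping_genes(cand, genes)
    same = [g for g in overlapping if g.strand == cand.strand]
    if not overlapping:
        return "intergenic"
    if not same:
        return "antisense"
    for g in same:
        exons = sorted(g.exons)
        if any(s <= cand.start and cand.end <= e for s, e in exons):
            return "one_exon"
        covered = [(s, e) for s, e in exons if cand.start <= s and e <= cand.end]
        if (len(covered) >= 2
                and any(s == cand.start for s, _ in exons)
                and any(e == cand.end for _, e in exons)):
            return "annot_exons"
        if any(s <= cand.start and cand.end <= e for s, e in g.introns):
            return "intronic"
    return "exon_intron"


def annotate_all(candidates: list[BackspliceCandidate],
                 genes: list[Gene]) -> None:
    for c in candidates:
        c.annotation = annotate_circ(c, genes)


def name_candidates(candidates: list[BackspliceCandidate]) -> dict[str, BackspliceCandidate]:
    """Assign novel_circ_NNNNNN names ordered by (chrom, start)."""
    ordered = sorted(candidates, key=lambda c: (c.chrom, c.start, c.end))
    return {f"novel_circ_{i + 1:06d}": c for i, c in enumerate(ordered)}


def support_matrix(named: dict[str, BackspliceCandidate],
                   samples: list[str]) -> pd.DataFrame:
    rows = {name: {s: c.support.get(s, 0) for s in samples}
            for name, c in named.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples).fillna(0)
    df.index.name = "circ_id"
    return df.astype(int)


def mapped_totals(reads: ReadSet, genome: ToyGenome,
                  k: int = ANCHOR_LEN) -> pd.Series:
    """Per-sample mapped-read totals for RPM (anchor-mappable reads)."""
    index = KmerIndex(genome, k)
    totals: dict[str, int] = {}
    for read in reads.reads:
        totals.setdefault(read.sample, 0)
        if index.map_anchor(read.sequence[:k]):
            totals[read.sample] += 1
    return pd.Series(totals, name="mapped")
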