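"""Synthetic-data generators with planted ground truth.

Every pipeline stage is exercised on data these generators emit: a toy
genome with planted GT/AG-flanked back-splice junctions and reads spanning
them, negative-binomial count matrices with planted fold changes, and
latent-factor-coupled expression planting the correlation structure the
ceRNA screen looks for (miRNA anti-correlated with both the circRNA and the
mRNA it targets; circRNA and mRNA positively coupled).

All randomness flows through :func:`numpy.random.default_rng` seeded
explicitly, so a fixed seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix, Gene, PlantedTruth, Read, ReadSet, ToyGenome
from .design import StudyDesign, make_design

_COMP = {"A", "C", "G", "T"}
_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# The 24 differentially expressed miRNA rows used as the direction fixture:
# (comparison, miRNA, log2 fold change, direction). Several miRNAs recur in
# more than one contrast; the planted group means satisfy every row of the
# table simultaneously (fold changes against a shared PK baseline compose).
TABLE2_ROWS: tuple[tuple[str, str, float, str], ...] = (
    ("DB_vs_PK", "miR-2995-x", 5.91, "up"),
    ("DB_vs_PK", "novel-m0026-5p", 5.87, "up"),
    ("DB_vs_PK", "gga-miR-3528", 4.21, "up"),
    ("DB_vs_PK", "miR-423-y", -6.51, "down"),
    ("DB_vs_PK", "novel-m0066-5p", -6.65, "down"),
    ("DB_vs_PK", "novel-m0067-5p", -6.65, "down"),
    ("LB_vs_PK", "miR-224-x", 8.72, "up"),
    ("LB_vs_PK", "miR-2995-x", 7.37, "up"),
    ("LB_vs_PK", "novel-m0026-5p", 7.37, "up"),
    ("LB_vs_PK", "gga-miR-2984-3p", -5.07, "down"),
    ("LB_vs_PK", "gga-miR-6552-3p", -7.4, "down"),
    ("LB_vs_PK", "gga-miR-6552-5p", -8.49, "down"),
    ("DP_vs_PK", "novel-m0093-3p", 5.32, "up"),
    ("DP_vs_PK", "novel-m0142-3p", 4.43, "up"),
    ("DP_vs_PK", "miR-2995-x", 3.84, "up"),
    ("DP_vs_PK", "miR-484-x", -3.28, "down"),
    ("DP_vs_PK", "gga-miR-6544-5p", -4.51, "down"),
    ("DP_vs_PK", "novel-m0096-3p", -5.14, "down"),
    ("DB_vs_DP", "novel-m0066-5p", 5.88, "up"),
    ("DB_vs_DP", "novel-m0067-5p", 5.88, "up"),
    ("DB_vs_DP", "gga-miR-6516-3p", 5.17, "up"),
    ("DB_vs_DP", "gga-miR-217-5p", -3.69, "down"),
    ("DB_vs_DP", "novel-m0136-5p", -4.4, "down"),
    ("DB_vs_DP", "gga-miR-6544-5p", -5.09, "down"),
)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + phi*mu^2; Poisson at phi == 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(design: StudyDesign,
                    truth: PlantedTruth,
                    n_null: int = 200,
                    baseline_mean: float = 100.0,
                    dispersion: float = 0.1,
                    seed: int = 0,
                    features: list[str] | None = None,
                    feature_spread_sd: float = 0.0) -> CountMatrix:
    """Negative-binomial counts with the fold changes in ``truth`` planted.

    For a feature planted in comparison "A_vs_B" with signed log2FC, group A's
    mean is baseline * 2^log2FC and every other group sits at baseline, so
    the planted fold change is expressed in the named (first) group relative
    to the control. ``feature_spread_sd`` optionally scatters per-feature
    baselines on the log scale for more realistic mean-variance structure.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0 (use a small value for ~Poisson)")
    if baseline_mean <= 0:
        raise ValueError("baseline_mean must be > 0")
    rng = np.random.default_rng(seed)

    if features is None:
        features = sorted(truth.de_features) + [f"null_{i:05d}" for i in range(n_null)]
    unknown = set(truth.de_features) - set(features)
    if unknown:
        raise ValueError(f"truth references unknown features: {sorted(unknown)[:5]}")

    # group-level log2 offsets per feature; comparisons compose against a
    # shared control, so a feature may legitimately appear in several rows
    # (constraint a_vs_b with fold f pins offset[a] = offset[b] + f; whichever
    # side is still free is solved for, and both-pinned rows must agree)
    offsets: dict[str, dict[str, float]] = {}
    for feat, planted in truth.de_features.items():
        rows = planted if isinstance(planted, list) else [planted]
        offs = offsets.setdefault(feat, {})
        for comparison, lfc in rows:
            a, b = comparison.split("_vs_")
            if a in offs and b in offs:
                if abs(offs[a] - offs[b] - lfc) > 1e-9:
                    raise ValueError(
                        f"{feat}: inconsistent planted fold changes at {comparison}")
            elif a in offs:
                offs[b] = offs[a] - lfc
            else:
                offs[a] = offs.get(b, 0.0) + lfc

    samples = design.samples
    groups = [design.group_of(s) for s in samples]
    base = np.full(len(features), float(baseline_mean))
    if feature_spread_sd > 0:
        base = base * np.exp(rng.normal(0.0, feature_spread_sd, size=len(features)))

    mat = np.zeros((len(features), len(samples)), dtype=np.int64)
    for j, (s, g) in enumerate(zip(samples, groups)):
        mu = base.copy()
        for i, feat in enumerate(features):
            off = offsets.get(feat, {}).get(g)
            if off is not None:
                mu[i] = base[i] * 2.0 ** off
        mat[:, j] = _nb_draw(rng, mu, dispersion)
    counts = pd.DataFrame(mat, index=pd.Index(features, name="feature"),
                          columns=samples)
    return CountMatrix(counts=counts, design=design)


# ---------------------------------------------------------------------------
# ceRNA structure


def make_cerna_truth(n_triples: int = 15,
                     n_decoys: int = 200,
                     decoy_targets: int = 3,
                     seed: int = 0) -> PlantedTruth:
    """Plant ceRNA triples plus independent decoy features with decoy edges.

    Each planted triple gets its own circRNA/miRNA/mRNA trio wired so the
    miRNA targets both partners. Decoy features are split evenly across the
    three RNA classes and each decoy miRNA is wired to ``decoy_targets``
    random decoy circRNAs and mRNAs, so the correlation screen is exercised
    on null edges too (otherwise no decoy could ever be emitted).
    """
    rng = np.random.default_rng(seed)
    triples = [(f"circ_T{i:03d}", f"miR-T{i:03d}", f"gene_T{i:03d}")
               for i in range(n_triples)]
    edges: dict[str, set[str]] = {}
    for circ, mir, mrna in triples:
        edges.setdefault(mir, set()).update({circ, mrna})

    n_mir = n_decoys // 3
    n_circ = (n_decoys - n_mir + 1) // 2
    n_mrna = n_decoys - n_mir - n_circ
    d_mir = [f"miR-D{i:03d}" for i in range(n_mir)]
    d_circ = [f"circ_D{i:03d}" for i in range(n_circ)]
    d_mrna = [f"gene_D{i:03d}" for i in range(n_mrna)]
    for mir in d_mir:
        chosen_c = rng.choice(len(d_circ), size=min(decoy_targets, len(d_circ)),
                              replace=False)
        chosen_m = rng.choice(len(d_mrna), size=min(decoy_targets, len(d_mrna)),
                              replace=False)
        edges.setdefault(mir, set()).update(d_circ[i] for i in chosen_c)
        edges[mir].update(d_mrna[i] for i in chosen_m)

    return PlantedTruth(target_edges=edges, cerna_triples=triples)


def _rna_class(feature: str) -> str:
    low = feature.lower()
    if low.startswith("circ"):
        return "circ"
    if low.startswith("mir") or low.startswith("gga-mir") or low.startswith("novel-m"):
        return "mirna"
    return "mrna"


def simulate_cerna_expression(design: StudyDesign,
                              truth: PlantedTruth,
                              coupling: float = 0.9,
                              noise_sd: float = 0.2,
                              baseline_mean: float = 500.0,
                              seed: int = 0) -> dict[str, CountMatrix]:
    """Counts with the correlation signs of the ceRNA model planted.

    One latent per-sample signal z is drawn per planted miRNA; the miRNA's
    abundance rises with z while its targeted circRNA and mRNA fall, all on
    the log scale: count = round(baseline * exp(+-coupling*z + noise_sd*eps)).
    At coupling 1 and vanishing noise the planted miRNA/partner Spearman is
    exactly -1 and the circRNA/mRNA Spearman exactly +1; decoys are
    independent of every latent. Returns one CountMatrix per RNA class
    ("mirna", "circ", "mrna").
    """
    if not (0 < coupling <= 1):
        raise ValueError("coupling must be in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if design.n_samples < 6:
        raise ValueError("need >= 6 samples for a meaningful Spearman screen")
    rng = np.random.default_rng(seed)
    samples = design.samples
    n = len(samples)

    features: set[str] = set()
    for mir, targets in truth.target_edges.items():
        features.add(mir)
        features.update(targets)
    for trip in truth.cerna_triples:
        features.update(trip)

    planted_mir = {mir for _, mir, _ in truth.cerna_triples}
    partner_of: dict[str, str] = {}  # partner feature -> its driving miRNA
    for circ, mir, mrna in truth.cerna_triples:
        partner_of[circ] = mir
        partner_of[mrna] = mir

    latent = {mir: rng.normal(0.0, 1.0, size=n) for mir in sorted(planted_mir)}

    out: dict[str, dict[str, np.ndarray]] = {"mirna": {}, "circ": {}, "mrna": {}}
    for feat in sorted(features):
        eps = rng.normal(0.0, 1.0, size=n) * noise_sd
        if feat in planted_mir:
            log_ex = coupling * latent[feat] + eps
        elif feat in partner_of:
            log_ex = -coupling * latent[partner_of[feat]] + eps
        else:  # decoy: its own independent signal of comparable spread
            log_ex = rng.normal(0.0, 1.0, size=n)
        counts = np.round(baseline_mean * np.exp(log_ex)).astype(np.int64)
        # rank tie-breaker: rounding can collide at small counts, which would
        # spoil the exact +-1 correlations promised at zero noise; adding the
        # within-feature rank (< n counts) keeps counts strictly monotone in
        # the feature's own log-expression
        counts += np.argsort(np.argsort(log_ex))
        out[_rna_class(feat)][feat] = counts

    result: dict[str, CountMatrix] = {}
    for klass, rows in out.items():
        df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
        df.index.name = "feature"
        result[klass] = CountMatrix(counts=df.sort_index(), design=design)
    return result


# ---------------------------------------------------------------------------
# toy genome + back-splice reads

ANCHOR_LEN = 20

_FLANKS = {"+": ("AG", "GT"), "-": ("AC", "CT")}  # (before start, after end)


def _plant_flanks(seq: list[str], start: int, end: int, strand: str) -> None:
    before, after = _FLANKS[strand]
    seq[start - 2:start] = list(before)
    seq[end:end + 2] = list(after)


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return list(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _make_gene(rng: np.random.Generator, gene_id: str, chrom: str, start: int,
               n_exons: int, strand: str) -> Gene:
    pos = start
    exons = []
    for _ in range(n_exons):
        elen = int(rng.integers(150, 300))
        exons.append((pos, pos + elen))
        pos += elen + int(rng.integers(150, 300))
    return Gene(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons)


def simulate_genome_and_reads(n_genes: int = 30,
                              n_circ: int = 30,
                              read_length: int = 100,
                              junction_depth: int = 3,
                              n_linear: int = 1000,
                              design: StudyDesign | None = None,
                              anchor_len: int = ANCHOR_LEN,
                              seed: int = 0) -> tuple[ToyGenome, ReadSet, PlantedTruth]:
    """Toy genome, back-splice reads at planted GT/AG junctions, linear reads.

    Each planted circRNA contributes ``junction_depth`` distinct reads that
    cross its back-splice point at distinct offsets (so unique support is
    exactly ``junction_depth`` by construction); breakpoints are written
    into the genome with canonical splice flanks (AG upstream of the
    acceptor, GT downstream of the donor, reverse-complemented for minus-
    strand circles). Background reads are collinear genome windows.
    """
    if read_length < 2 * anchor_len:
        raise ValueError(f"read_length must be >= {2 * anchor_len}")
    if junction_depth < 2:
        raise ValueError("junction_depth must be >= 2 to pass the support filter")
    if n_circ > n_genes:
        raise ValueError("need at least one gene per planted circRNA")
    rng = np.random.default_rng(seed)
    design = design or make_design()

    chrom = "chr1"
    genes: list[Gene] = []
    pos = 500
    for i in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        g = _make_gene(rng, f"gene{i + 1:03d}", chrom, pos,
                       n_exons=int(rng.integers(3, 6)), strand=strand)
        genes.append(g)
        pos = g.end + int(rng.integers(400, 800))
    genome_len = pos + 500
    seq = _random_seq(rng, genome_len)

    # plant circles on distinct genes, spanning whole exons (annot_exons-like)
    junctions: list[tuple[str, int, int, str]] = []
    gene_idx = rng.permutation(n_genes)[:n_circ]
    for gi in sorted(gene_idx):
        g = genes[gi]
        ex = sorted(g.exons)
        i = int(rng.integers(0, len(ex) - 1))
        j = int(rng.integers(i + 1, len(ex)))
        start, end = ex[i][0], ex[j][1]
        if end - start < read_length:  # widen to cover a full read
            end = start + read_length + 20
        _plant_flanks(seq, start, end, g.strand)
        junctions.append((chrom, start, end, g.strand))

    genome = ToyGenome(sequences={chrom: "".join(seq)}, genes=genes)
    gseq = genome.sequences[chrom]

    reads: list[Read] = []
    samples = design.samples
    for ji, (c, start, end, strand) in enumerate(junctions):
        sample = samples[ji % len(samples)]
        max_a = read_length - anchor_len
        if junction_depth > max_a - anchor_len + 1:
            raise ValueError("junction_depth exceeds the number of distinct "
                             "junction-spanning offsets the read length allows")
        offsets = np.linspace(anchor_len, max_a, num=junction_depth).astype(int)
        offsets = sorted(set(int(a) for a in offsets))
        extra = anchor_len
        while len(offsets) < junction_depth:  # ensure distinct offsets
            extra += 1
            if anchor_len <= extra <= max_a and extra not in offsets:
                offsets.append(extra)
        for ri, a in enumerate(sorted(offsets[:junction_depth])):
            b = read_length - a
            s = gseq[end - a:end] + gseq[start:start + b]
            if strand == "-":
                s = revcomp(s)
            reads.append(Read(f"bsj_{ji:04d}_{ri}", sample, s))

    for li in range(n_linear):
        p = int(rng.integers(0, genome_len - read_length))
        s = gseq[p:p + read_length]
        if rng.random() < 0.5:
            s = revcomp(s)
        reads.append(Read(f"lin_{li:06d}", samples[li % len(samples)], s))

    truth = PlantedTruth(junctions=junctions)
    return genome, ReadSet(reads=reads, read_length=read_length), truth


def class_fixture_genome(read_length: int = 100,
                         junction_depth: int = 3,
                         anchor_len: int = ANCHOR_LEN,
                         seed: int = 0) -> tuple[ToyGenome, ReadSet, PlantedTruth, dict[str, str]]:
    """A small genome planting one circle of each annotation class.

    Returns the genome, reads, truth and a map junction key
    "chrom:start-end:strand" -> expected class, covering annot_exons,
    one_exon, exon_intron, intronic, antisense and intergenic.
    """
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    genome_len = 12000
    seq = _random_seq(rng, genome_len)

    # one forward gene with three roomy exons, and one reverse gene
    fwd = Gene("geneF", chrom, "+",
               exons=[(500, 800), (1100, 1400), (1700, 2000)])
    rev = Gene("geneR", chrom, "-", exons=[(4000, 4400), (4800, 5200)])
    genes = [fwd, rev]

    spans: list[tuple[int, int, str, str]] = [
        (500, 1400, "+", "annot_exons"),   # exon1 start .. exon2 end
        (540, 760, "+", "one_exon"),       # inside exon1
        (1150, 1550, "+", "exon_intron"),  # exon2 into intron2
        (820, 1060, "+", "intronic"),      # wholly inside intron1
        (4050, 4350, "+", "antisense"),    # inside geneR's exon, opposite strand
        (8000, 8400, "+", "intergenic"),   # annotation desert
    ]
    junctions = []
    expected: dict[str, str] = {}
    for start, end, strand, klass in spans:
        _plant_flanks(seq, start, end, strand)
        junctions.append((chrom, start, end, strand))
        expected[f"{chrom}:{start}-{end}:{strand}"] = klass

    genome = ToyGenome(sequences={chrom: "".join(seq)}, genes=genes)
    gseq = genome.sequences[chrom]
    design = make_design()
    reads: list[Read] = []
    for ji, (c, start, end, strand) in enumerate(junctions):
        sample = design.samples[ji % len(design.samples)]
        for ri in range(junction_depth):
            a = anchor_len + ri * ((read_length - 2 * anchor_len) // max(1, junction_depth - 1))
            b = read_length - a
            s = gseq[end - a:end] + gseq[start:start + b]
            if strand == "-":
                s = revcomp(s)
            reads.append(Read(f"bsj_{ji}_{ri}", sample, s))
    truth = PlantedTruth(junctions=junctions)
    return genome, ReadSet(reads=reads, read_length=read_length), truth, expected


# ---------------------------------------------------------------------------
# direction fixture for the printed fold-change table


def table2_truth() -> PlantedTruth:
    """Planted truth holding every printed (comparison, log2FC) row."""
    de: dict[str, list[tuple[str, float]]] = {}
    for comparison, mirna, lfc, _direction in TABLE2_ROWS:
        de.setdefault(mirna, []).append((comparison, lfc))
    return PlantedTruth(de_features=de)  # type: ignore[arg-type]


def table2_fixture(seed: int = 0,
                   n_null: int = 200,
                   baseline_mean: float = 1000.0,
                   dispersion: float = 0.1) -> tuple[CountMatrix, pd.DataFrame]:
    """Counts planting the 24 printed miRNA fold changes, plus null features.

    The same miRNA may be printed in several contrasts; its group means are
    chosen so every one of its printed rows holds at once (offsets relative
    to the shared control compose). The baseline of 1000 reads reflects a
    deep small-RNA library and keeps the far side of the largest printed
    fold changes (|log2FC| up to 8.72, i.e. ~1/420 of baseline) above the
    detection floor. Returns the counts and the expected per-(feature,
    comparison) classification table with columns (feature, comparison,
    log2fc, expected); null features are expected "ns" in every contrast.
    """
    design = make_design()
    truth = table2_truth()
    cm = simulate_counts(design, truth, n_null=n_null,
                         baseline_mean=baseline_mean, dispersion=dispersion,
                         seed=seed)
    rows = [
        {"feature": mirna, "comparison": comparison, "log2fc": lfc,
         "expected": direction}
        for comparison, mirna, lfc, direction in TABLE2_ROWS
    ]
    comparisons = sorted({c for c, *_ in TABLE2_ROWS})
    for feat in cm.features:
        if str(feat).startswith("null_"):
            for comparison in comparisons:
                rows.append({"feature": feat, "comparison": comparison,
                             "log2fc": 0.0, "expected": "ns"})
    return cm, pd.DataFrame(rows)
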