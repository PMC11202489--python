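"""File formats: FASTA/FASTQ (Biopython), GTF (gffutils), TSV tables.

Everything the generators emit is re-readable by the readers here
(round-trip identity), which the test suite asserts.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import CountMatrix, Gene, PlantedTruth, Read, ReadSet, ToyGenome
from .design import StudyDesign, make_design


# -- FASTA / FASTQ ----------------------------------------------------------

def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq_per_sample(reads: ReadSet, directory) -> Path:
    """One FASTQ per sample (dummy quality 'I') plus a sample-map TSV.

    Returns the path of the sample map (sample, fastq columns).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample, sample_reads in sorted(reads.by_sample().items()):
        fq = directory / f"{sample}.fastq"
        records = []
        for r in sample_reads:
            rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
            records.append(rec)
        SeqIO.write(records, str(fq), "fastq")
        rows.append({"sample": sample, "fastq": fq.name})
    map_path = directory / "samples.tsv"
    pd.DataFrame(rows).to_csv(map_path, sep="\t", index=False)
    return map_path


def read_fastq_sample_map(map_path) -> ReadSet:
    map_path = Path(map_path)
    table = pd.read_csv(map_path, sep="\t")
    reads: list[Read] = []
    length = 0
    for _, row in table.iterrows():
        fq = map_path.parent / row["fastq"]
        for rec in SeqIO.parse(str(fq), "fastq"):
            seq = str(rec.seq)
            length = max(length, len(seq))
            reads.append(Read(read_id=rec.id, sample=str(row["sample"]),
                              sequence=seq))
    return ReadSet(reads=reads, read_length=length)


# -- GTF --------------------------------------------------------------------

def write_gtf(genome: ToyGenome, path) -> None:
    """Emit gene + exon records; GTF is 1-based inclusive."""
    with open(path, "w") as fh:
        for g in genome.genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write("\t".join([g.chrom, "shellnet", "gene",
                                str(g.start + 1), str(g.end), ".", g.strand,
                                ".", attrs]) + "\n")
            for s, e in sorted(g.exons):
                fh.write("\t".join([g.chrom, "shellnet", "exon",
                                    str(s + 1), str(e), ".", g.strand,
                                    ".", attrs]) + "\n")


def read_gtf(path) -> list[Gene]:
    """Parse exon records back into Gene objects (0-based half-open)."""
    import gffutils
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, disable_infer_genes=True,
                            disable_infer_transcripts=True)
    genes: dict[str, Gene] = {}
    for feat in db.features_of_type("exon", order_by="start"):
        gid = feat.attributes["gene_id"][0]
        g = genes.setdefault(gid, Gene(gene_id=gid, chrom=feat.seqid,
                                       strand=feat.strand, exons=[]))
        g.exons.append((feat.start - 1, feat.end))
    return [genes[k] for k in sorted(genes)]


# -- TSV tables -------------------------------------------------------------

def write_counts(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t")


def read_counts(path, design: StudyDesign | None = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(counts=df, design=design)


def write_truth(truth: PlantedTruth, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    de_rows = []
    for feat, planted in truth.de_features.items():
        rows = planted if isinstance(planted, list) else [planted]
        for comparison, lfc in rows:
            de_rows.append({"feature": feat, "comparison": comparison,
                            "log2fc": lfc})
    pd.DataFrame(de_rows, columns=["feature", "comparison", "log2fc"]).to_csv(
        directory / "truth_de.tsv", sep="\t", index=False)
    pd.DataFrame(truth.junctions,
                 columns=["chrom", "start", "end", "strand"]).to_csv(
        directory / "truth_junctions.tsv", sep="\t", index=False)
    edge_rows = [{"mirna": m, "target": t}
                 for m, targets in sorted(truth.target_edges.items())
                 for t in sorted(targets)]
    pd.DataFrame(edge_rows, columns=["mirna", "target"]).to_csv(
        directory / "truth_edges.tsv", sep="\t", index=False)
    pd.DataFrame(truth.cerna_triples,
                 columns=["circ", "mirna", "mrna"]).to_csv(
        directory / "truth_triples.tsv", sep="\t", index=False)


def read_truth(directory) -> PlantedTruth:
    directory = Path(directory)
    de: dict[str, list[tuple[str, float]]] = {}
    de_tab = pd.read_csv(directory / "truth_de.tsv", sep="\t")
    for _, row in de_tab.iterrows():
        de.setdefault(str(row["feature"]), []).append(
            (str(row["comparison"]), float(row["log2fc"])))
    jx_tab = pd.read_csv(directory / "truth_junctions.tsv", sep="\t")
    junctions = [(str(r["chrom"]), int(r["start"]), int(r["end"]), str(r["strand"]))
                 for _, r in jx_tab.iterrows()]
    edge_tab = pd.read_csv(directory / "truth_edges.tsv", sep="\t")
    edges: dict[str, set[str]] = {}
    for _, row in edge_tab.iterrows():
        edges.setdefault(str(row["mirna"]), set()).add(str(row["target"]))
    tr_tab = pd.read_csv(directory / "truth_triples.tsv", sep="\t")
    triples = [(str(r["circ"]), str(r["mirna"]), str(r["mrna"]))
               for _, r in tr_tab.iterrows()]
    return PlantedTruth(de_features=de, junctions=junctions,  # type: ignore[arg-type]
                        target_edges=edges, cerna_triples=triples)


def write_bed6(named_candidates: dict, path) -> None:
    """BED6 of junctions (0-based half-open), score = max unique support."""
    rows = []
    for name, c in named_candidates.items():
        rows.append([c.chrom, c.start, c.end, name, c.max_support, c.strand])
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_bed6(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "name", "score", "strand"])
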