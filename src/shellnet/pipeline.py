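"""End-to-end orchestration: synthetic inputs -> junctions -> expression ->
DE -> targets -> ceRNA network -> enrichment, from one config, fully seeded.

All randomness flows from one master seed through per-stage child seeds
(numpy SeedSequence), so a fixed seed reproduces every output file
byte-for-byte. Each run writes a manifest recording the seed, a parameter
hash and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circdetect, cerna, de, enrichment, io, quantify, synthetic, targets
from .containers import CountMatrix, PlantedTruth
from .design import DEFAULT_COMPARISONS, make_design

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds, design and seed for a full synthetic run."""

    seed: int = 0
    out_dir: str = "shellnet_out"
    replicates: tuple[int, int, int, int] = (3, 3, 4, 3)
    # junction calling
    n_genes: int = 30
    n_circ: int = 30
    read_length: int = 100
    junction_depth: int = 3
    n_linear: int = 1000
    anchor_len: int = 20
    min_unique: int = 2
    # differential expression
    de_mode: str = "pvalue"
    de_alpha: float = 0.05
    lfc_cutoff: float = 1.0
    # ceRNA screens
    n_triples: int = 15
    n_decoys: int = 200
    coupling: float = 0.9
    noise_sd: float = 0.2
    neg_cutoff: float = -0.5
    pos_cutoff: float = 0.5
    cerna_alpha: float = 0.05
    top_k: int = 10
    # enrichment
    n_terms: int = 12
    enrich_top: int = 20

    def validate(self) -> None:
        if not (0 < self.coupling <= 1):
            raise ValueError("coupling must be in (0, 1]")
        if self.read_length < 2 * self.anchor_len:
            raise ValueError("read_length must be >= 2 x anchor length")
        if self.min_unique < 1 or self.top_k < 1:
            raise ValueError("min_unique and top_k must be >= 1")
        if self.de_mode not in ("fdr", "pvalue"):
            raise ValueError("de_mode must be 'fdr' or 'pvalue'")

    def param_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "replicates" in data:
            data["replicates"] = tuple(data["replicates"])
        return cls(**data)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2 ** 31)) for s in state]


@dataclass
class RunManifest:
    seed: int
    param_hash: str
    stage_counts: dict[str, int] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "param_hash": self.param_hash,
                       "stage_counts": self.stage_counts}, fh, indent=2,
                      sort_keys=True)
            fh.write("\n")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage on synthetic inputs and write all outputs.

    Stage order: synthetic data -> junction calling -> quantification ->
    differential expression -> target import -> ceRNA network ->
    enrichment -> truth validation. A stage failure raises with the stage
    name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = RunManifest(seed=config.seed, param_hash=config.param_hash())
    design = make_design(config.replicates)

    stage = "synthetic_data"
    try:
        genome, reads, junction_truth = synthetic.simulate_genome_and_reads(
            n_genes=config.n_genes, n_circ=config.n_circ,
            read_length=config.read_length,
            junction_depth=config.junction_depth, n_linear=config.n_linear,
            design=design, anchor_len=config.anchor_len, seed=seeds[0])
        io.write_fasta(genome.sequences, out / "genome.fa")
        io.write_gtf(genome, out / "annotation.gtf")
        io.write_fastq_per_sample(reads, out / "reads")

        cerna_truth = synthetic.make_cerna_truth(
            n_triples=config.n_triples, n_decoys=config.n_decoys,
            seed=seeds[1])
        expr = synthetic.simulate_cerna_expression(
            design, cerna_truth, coupling=config.coupling,
            noise_sd=config.noise_sd, seed=seeds[2])
        de_counts, expected_de = synthetic.table2_fixture(seed=seeds[3])
        truth = PlantedTruth(
            de_features=synthetic.table2_truth().de_features,
            junctions=junction_truth.junctions,
            target_edges=cerna_truth.target_edges,
            cerna_triples=cerna_truth.cerna_triples)
        io.write_truth(truth, out / "truth")
        for klass, cm in expr.items():
            io.write_counts(cm, out / f"counts_{klass}.tsv")
        io.write_counts(de_counts, out / "counts_mirna_de.tsv")
        manifest.stage_counts["reads"] = len(reads.reads)
        manifest.stage_counts["planted_junctions"] = len(truth.junctions)
        manifest.stage_counts["planted_triples"] = len(truth.cerna_triples)

        stage = "circ_detect"
        candidates, counters = circdetect.detect_backsplices(
            reads, genome, k=config.anchor_len)
        kept = circdetect.filter_candidates(candidates, config.min_unique)
        circdetect.annotate_all(kept, genome.genes)
        named = circdetect.name_candidates(kept)
        io.write_bed6(named, out / "junctions.bed")
        support = circdetect.support_matrix(named, design.samples)
        support.to_csv(out / "junction_support.tsv", sep="\t")
        totals = circdetect.mapped_totals(reads, genome, k=config.anchor_len)
        rpm_mat = quantify.rpm(support, totals.reindex(design.samples).fillna(1))
        rpm_mat.to_csv(out / "junction_rpm.tsv", sep="\t")
        manifest.stage_counts["junctions_called"] = len(kept)
        manifest.stage_counts["ambiguous_reads"] = counters.get("ambiguous", 0)

        stage = "quantify"
        mirna_tpm = quantify.tpm(expr["mirna"])
        mirna_tpm.to_csv(out / "tpm_mirna.tsv", sep="\t")
        rng_q = np.random.default_rng(seeds[4])
        lengths = pd.Series(
            rng_q.integers(500, 3000, size=len(expr["mrna"].features)),
            index=expr["mrna"].features, name="length")
        mrna_cm = CountMatrix(counts=expr["mrna"].counts, design=design,
                              lengths=lengths)
        mrna_fpkm = quantify.fpkm(mrna_cm)
        mrna_fpkm.to_csv(out / "fpkm_mrna.tsv", sep="\t")
        circ_cpm = quantify.tpm(expr["circ"])
        circ_cpm.to_csv(out / "rpm_circ.tsv", sep="\t")

        stage = "de_analysis"
        de_table = de.run_de(de_counts, DEFAULT_COMPARISONS,
                             de.DEOptions(mode=config.de_mode,
                                          alpha=config.de_alpha,
                                          lfc_cutoff=config.lfc_cutoff))
        de_table.to_csv(out / "de_mirna.tsv", sep="\t", index=False)
        expected_de.to_csv(out / "de_expected.tsv", sep="\t", index=False)
        manifest.stage_counts["de_significant"] = int(
            (de_table["status"] != "ns").sum())

        stage = "target_predict"
        edge_rows = [{"mirna": m, "target": t}
                     for m, ts in sorted(cerna_truth.target_edges.items())
                     for t in sorted(ts)]
        pd.DataFrame(edge_rows).to_csv(out / "target_edges_in.tsv",
                                       sep="\t", index=False)
        edges = targets.load_target_table(out / "target_edges_in.tsv")
        target_map = targets.edges_to_map(edges)
        manifest.stage_counts["target_edges"] = len(edges)

        stage = "cerna_network"
        expr_mirna = expr["mirna"].counts.astype(float)
        expr_circ = expr["circ"].counts.astype(float)
        expr_mrna = expr["mrna"].counts.astype(float)
        rna_expr = pd.concat([expr_circ, expr_mrna])
        neg = cerna.screen_negative_pairs(expr_mirna, rna_expr, target_map,
                                          cutoff=config.neg_cutoff)
        triples = cerna.build_cerna_triples(
            neg, expr_circ, expr_mrna, pos_cutoff=config.pos_cutoff,
            alpha=config.cerna_alpha)
        cerna.triples_to_frame(triples).to_csv(out / "cerna_triples.tsv",
                                               sep="\t", index=False)
        network = cerna.build_network(triples)
        cerna.network_edge_table(network).to_csv(out / "network_edges.tsv",
                                                 sep="\t", index=False)
        cerna.sankey_table(triples, network, config.top_k).to_csv(
            out / "network_sankey.tsv", sep="\t", index=False)
        ranked = cerna.connectivity_rank(network, config.top_k)
        rank_rows = [{"node_type": t, "node": n, "degree": d}
                     for t, nodes in ranked.items() for n, d in nodes]
        pd.DataFrame(rank_rows,
                     columns=["node_type", "node", "degree"]).to_csv(
            out / "connectivity.tsv", sep="\t", index=False)
        manifest.stage_counts["neg_pairs"] = len(neg)
        manifest.stage_counts["cerna_triples"] = len(triples)

        stage = "enrichment"
        rng_e = np.random.default_rng(seeds[5])
        mrna_ids = sorted(expr["mrna"].features)
        members = {}
        for i in range(config.n_terms):
            size = int(rng_e.integers(8, 25))
            pick = rng_e.choice(len(mrna_ids), size=min(size, len(mrna_ids)),
                                replace=False)
            members[f"TERM:{i:04d}"] = {mrna_ids[j] for j in pick}
        term_map = enrichment.TermMap(members=members)
        term_rows = [{"term": t, "gene": g}
                     for t, genes in sorted(members.items())
                     for g in sorted(genes)]
        pd.DataFrame(term_rows).to_csv(out / "term_map.tsv", sep="\t",
                                       index=False)
        gene_set = {t.mrna for t in triples} & term_map.universe
        results = enrichment.enrich(gene_set, term_map)
        results.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        enrichment.top_terms(results, config.enrich_top).to_csv(
            out / "enrichment_top.tsv", sep="\t", index=False)
        manifest.stage_counts["terms_tested"] = len(results)

        stage = "validate"
        report = validate_against_truth(out, truth)
        with open(out / "recovery.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest.stage_counts["recovered_triples"] = int(
            round(report["triple_sensitivity"] * len(truth.cerna_triples)))
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.write(out / "manifest.json")
    return manifest


def validate_against_truth(out_dir, truth: PlantedTruth) -> dict[str, float]:
    """Recovery report: junction, DE and ceRNA-triple metrics vs truth."""
    out = Path(out_dir)
    report: dict[str, float] = {}

    bed = io.read_bed6(out / "junctions.bed")
    called = {(r.chrom, int(r.start), int(r.end), r.strand)
              for r in bed.itertuples()}
    planted = set(truth.junctions)
    report["junction_sensitivity"] = (
        len(called & planted) / len(planted) if planted else 1.0)
    report["junction_precision"] = (
        len(called & planted) / len(called) if called else 1.0)

    de_table = pd.read_csv(out / "de_mirna.tsv", sep="\t")
    de_hits = 0
    de_total = 0
    for feat, planted_rows in truth.de_features.items():
        rows = planted_rows if isinstance(planted_rows, list) else [planted_rows]
        for comparison, lfc in rows:
            de_total += 1
            sub = de_table[(de_table["feature"] == feat)
                           & (de_table["comparison"] == comparison)]
            if sub.empty:
                continue
            want = "up" if lfc > 0 else "down"
            if sub.iloc[0]["status"] == want:
                de_hits += 1
    report["de_sensitivity"] = de_hits / de_total if de_total else 1.0

    tri = pd.read_csv(out / "cerna_triples.tsv", sep="\t")
    emitted = {(str(r.circ), str(r.mirna), str(r.mrna))
               for r in tri.itertuples()}
    planted_tri = set(truth.cerna_triples)
    report["triple_sensitivity"] = (
        len(emitted & planted_tri) / len(planted_tri) if planted_tri else 1.0)
    report["triple_decoy_rate"] = (
        len(emitted - planted_tri) / len(emitted) if emitted else 0.0)
    return report


def demo(seed: int = 7, out_dir: str = "shellnet_demo") -> RunManifest:
    """One-command synthetic demo with default parameters."""
    return run_pipeline(PipelineConfig(seed=seed, out_dir=out_dir))
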