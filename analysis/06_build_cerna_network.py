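#!/usr/bin/env python
"""Screen correlations, test shared miRNAs, assemble the ceRNA network.

The three screens: miRNA-target Spearman <= -0.5, circRNA-mRNA Spearman
> 0.5, shared-miRNA hypergeometric p < 0.05. Emits the triples table,
Cytoscape edge list, Sankey flow table and per-type connectivity ranking,
and scores triple recovery against the planted truth.
"""

from pathlib import Path

import pandas as pd

from shellnet import cerna, io, targets

RUN = Path("results/run")


def main() -> None:
    expr_mirna = pd.read_csv(RUN / "counts_mirna.tsv", sep="\t", index_col=0)
    expr_circ = pd.read_csv(RUN / "counts_circ.tsv", sep="\t", index_col=0)
    expr_mrna = pd.read_csv(RUN / "counts_mrna.tsv", sep="\t", index_col=0)
    edges = targets.load_target_table(RUN / "target_edges.tsv")
    target_map = targets.edges_to_map(edges)

    rna = pd.concat([expr_circ, expr_mrna]).astype(float)
    neg = cerna.screen_negative_pairs(expr_mirna.astype(float), rna, target_map)
    triples = cerna.build_cerna_triples(neg, expr_circ.astype(float),
                                        expr_mrna.astype(float))
    cerna.triples_to_frame(triples).to_csv(RUN / "cerna_triples.tsv",
                                           sep="\t", index=False)
    network = cerna.build_network(triples)
    cerna.network_edge_table(network).to_csv(RUN / "network_edges.tsv",
                                             sep="\t", index=False)
    cerna.sankey_table(triples, network, top_k=10).to_csv(
        RUN / "network_sankey.tsv", sep="\t", index=False)
    ranked = cerna.connectivity_rank(network, top_k=10)
    pd.DataFrame([{"node_type": t, "node": n, "degree": d}
                  for t, nodes in ranked.items() for n, d in nodes]).to_csv(
        RUN / "connectivity.tsv", sep="\t", index=False)

    truth = io.read_truth(RUN / "truth")
    emitted = {(t.circ, t.mirna, t.mrna) for t in triples}
    planted = set(truth.cerna_triples)
    n_nodes = {t: len([n for n, d in network.nodes(data=True)
                       if d["node_type"] == t])
               for t in ("circRNA", "miRNA", "mRNA")}
    print(f"{len(neg)} negatively correlated target pairs -> "
          f"{len(triples)} ceRNA triples")
    print(f"network: {n_nodes['circRNA']} circRNAs, {n_nodes['miRNA']} miRNAs, "
          f"{n_nodes['mRNA']} mRNAs, {network.number_of_edges()} edges")
    print(f"recovered {len(emitted & planted)}/{len(planted)} planted triples; "
          f"{len(emitted - planted)} decoy triples emitted")
    if ranked["mRNA"]:
        top = ", ".join(f"{n} (deg {d})" for n, d in ranked["mRNA"][:3])
        print(f"top connectivity mRNAs: {top}")


if __name__ == "__main__":
    main()
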