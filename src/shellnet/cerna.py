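"""ceRNA network inference: correlation screens, shared-miRNA test, ranking.

The competing-endogenous-RNA logic: a circRNA that sponges a miRNA should
be anti-correlated with it, the miRNA anti-correlated with its mRNA
targets, and sponge and target therefore positively coupled. The screens
implement exactly that:

1. among predicted miRNA->RNA target pairs, keep those with Spearman
   rho <= -0.5 (non-strict);
2. pair circRNAs with mRNAs when their own Spearman rho > 0.5 (strict) and
   the overlap of their screened miRNA regulators is larger than chance by
   a one-sided hypergeometric test at p < 0.05 (raw p; no multiplicity
   correction by default, BH available behind a flag);
3. assemble the bipartite circRNA-miRNA / miRNA-mRNA network and rank
   nodes by connectivity (distinct regulatory partners).

The miRNA universe N for the hypergeometric test defaults to the distinct
miRNAs present in the screened negative-pair set; it can be widened to all
expressed miRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .stats import bh_adjust, hypergeom_sf_shared, spearman, spearman_matrix


@dataclass(frozen=True)
class CorrelationPair:
    a: str
    b: str
    rho: float
    n: int


@dataclass(frozen=True)
class CeRNATriple:
    circ: str
    mirna: str
    mrna: str
    rho_mir_circ: float
    rho_mir_mrna: float
    rho_circ_mrna: float
    shared: int        # m: miRNAs shared by the pair
    circ_mirnas: int   # n: screened miRNAs regulating the circRNA
    mrna_mirnas: int   # K: screened miRNAs regulating the mRNA
    universe: int      # N
    p: float


def _align(expr_a: pd.DataFrame, expr_b: pd.DataFrame) -> list[str]:
    shared = [s for s in expr_a.columns if s in set(expr_b.columns)]
    if not shared:
        raise ValueError("no shared samples between expression matrices")
    return shared


def screen_negative_pairs(expr_mirna: pd.DataFrame,
                          expr_rna: pd.DataFrame,
                          target_map: dict[str, set[str]],
                          cutoff: float = -0.5) -> list[CorrelationPair]:
    """Predicted target pairs with Spearman rho <= cutoff (non-strict).

    Only (miRNA, RNA) pairs present in ``target_map`` are tested, across
    the samples the two matrices share.
    """
    samples = _align(expr_mirna, expr_rna)
    kept: list[CorrelationPair] = []
    for mirna, targets in sorted(target_map.items()):
        if mirna not in expr_mirna.index:
            continue
        x = expr_mirna.loc[mirna, samples].to_numpy(dtype=float)
        for rna in sorted(targets):
            if rna not in expr_rna.index:
                continue
            y = expr_rna.loc[rna, samples].to_numpy(dtype=float)
            rho = spearman(x, y)
            if rho <= cutoff:
                kept.append(CorrelationPair(a=mirna, b=rna, rho=rho,
                                            n=len(samples)))
    return kept


def build_cerna_triples(neg_pairs: list[CorrelationPair],
                        expr_circ: pd.DataFrame,
                        expr_mrna: pd.DataFrame,
                        pos_cutoff: float = 0.5,
                        alpha: float = 0.05,
                        universe: int | None = None,
                        adjust: bool = False) -> list[CeRNATriple]:
    """Emit circRNA-miRNA-mRNA triples passing all three screens.

    A candidate circ-mRNA pair must share at least one screened miRNA; it
    survives if rho(circ, mRNA) > pos_cutoff (strict) and the shared-miRNA
    hypergeometric p < alpha (strict). One triple is emitted per (circ,
    miRNA, mRNA) with the pair-level statistics attached. ``universe``
    overrides N (e.g. all expressed miRNAs); ``adjust`` applies BH to the
    pair-level p-values before the alpha screen (off by default: the screen
    is conventionally run on raw p).
    """
    circ_ids = set(expr_circ.index)
    mrna_ids = set(expr_mrna.index)
    samples = _align(expr_circ, expr_mrna)

    rho_lookup: dict[tuple[str, str], float] = {(p.a, p.b): p.rho
                                                for p in neg_pairs}
    by_circ: dict[str, set[str]] = {}
    by_mrna: dict[str, set[str]] = {}
    for p in neg_pairs:
        if p.b in circ_ids:
            by_circ.setdefault(p.b, set()).add(p.a)
        if p.b in mrna_ids:
            by_mrna.setdefault(p.b, set()).add(p.a)
    screened_mirnas = {p.a for p in neg_pairs}
    N = universe if universe is not None else len(screened_mirnas)

    pairs: list[tuple[str, str, set[str], float, float]] = []
    for circ in sorted(by_circ):
        x = expr_circ.loc[circ, samples].to_numpy(dtype=float)
        for mrna in sorted(by_mrna):
            shared = by_circ[circ] & by_mrna[mrna]
            if not shared:
                continue
            y = expr_mrna.loc[mrna, samples].to_numpy(dtype=float)
            rho = spearman(x, y)
            if rho <= pos_cutoff:  # strict "> 0.5"
                continue
            p = hypergeom_sf_shared(len(shared), len(by_circ[circ]),
                                    len(by_mrna[mrna]), N)
            pairs.append((circ, mrna, shared, rho, p))

    if not pairs:
        return []
    pvec = np.array([p for *_, p in pairs])
    qvec = bh_adjust(pvec) if adjust else pvec
    triples: list[CeRNATriple] = []
    for (circ, mrna, shared, rho, p), q in zip(pairs, qvec):
        if q >= alpha:
            continue
        for mirna in sorted(shared):
            triples.append(CeRNATriple(
                circ=circ, mirna=mirna, mrna=mrna,
                rho_mir_circ=rho_lookup[(mirna, circ)],
                rho_mir_mrna=rho_lookup[(mirna, mrna)],
                rho_circ_mrna=rho,
                shared=len(shared),
                circ_mirnas=len(by_circ[circ]),
                mrna_mirnas=len(by_mrna[mrna]),
                universe=N, p=float(p)))
    return triples


NODE_TYPES = ("circRNA", "miRNA", "mRNA")


def build_network(triples: list[CeRNATriple]) -> nx.Graph:
    """Bipartite circ-miRNA / miRNA-mRNA graph from emitted triples."""
    g = nx.Graph()
    for t in triples:
        g.add_node(t.circ, node_type="circRNA")
        g.add_node(t.mirna, node_type="miRNA")
        g.add_node(t.mrna, node_type="mRNA")
        g.add_edge(t.circ, t.mirna, interaction="circ-miRNA")
        g.add_edge(t.mirna, t.mrna, interaction="miRNA-mRNA")
    return g


def connectivity_rank(network: nx.Graph, top_k: int = 10) -> dict[str, list[tuple[str, int]]]:
    """Per-type nodes ranked by degree (descending), ties lexicographic.

    Degree counts distinct regulatory partners in the bipartite network.
    Returns up to ``top_k`` (node, degree) rows per node type; an empty
    network yields empty rankings.
    """
    out: dict[str, list[tuple[str, int]]] = {t: [] for t in NODE_TYPES}
    for node, data in network.nodes(data=True):
        out[data["node_type"]].append((node, int(network.degree(node))))
    for t in NODE_TYPES:
        out[t] = sorted(out[t], key=lambda nd: (-nd[1], nd[0]))[:top_k]
    return out


def network_edge_table(network: nx.Graph) -> pd.DataFrame:
    """Cytoscape-importable edge list (source, interaction, target).

    circ-miRNA edges list the circRNA as source; miRNA-mRNA edges list the
    miRNA as source. Deterministically ordered.
    """
    rows = []
    for u, v, data in network.edges(data=True):
        interaction = data["interaction"]
        if interaction == "circ-miRNA":
            src, dst = (u, v) if network.nodes[u]["node_type"] == "circRNA" else (v, u)
        else:
            src, dst = (u, v) if network.nodes[u]["node_type"] == "miRNA" else (v, u)
        rows.append({"source": src, "interaction": interaction, "target": dst})
    df = pd.DataFrame(rows, columns=["source", "interaction", "target"])
    return df.sort_values(["interaction", "source", "target"]).reset_index(drop=True)


def network_from_edge_table(df: pd.DataFrame) -> nx.Graph:
    """Rebuild the network from an exported edge table (round trip)."""
    g = nx.Graph()
    for _, row in df.iterrows():
        src, interaction, dst = row["source"], row["interaction"], row["target"]
        if interaction == "circ-miRNA":
            g.add_node(src, node_type="circRNA")
            g.add_node(dst, node_type="miRNA")
        elif interaction == "miRNA-mRNA":
            g.add_node(src, node_type="miRNA")
            g.add_node(dst, node_type="mRNA")
        else:
            raise ValueError(f"unknown interaction type: {interaction!r}")
        g.add_edge(src, dst, interaction=interaction)
    return g


def sankey_table(triples: list[CeRNATriple], network: nx.Graph,
                 top_k: int = 10) -> pd.DataFrame:
    """Flow table (source, target, value) restricted to top-k ranked nodes.

    Values are the shared-miRNA counts of the underlying circ-mRNA pair,
    following the circ -> miRNA -> mRNA flow of the connectivity diagram.
    """
    ranked = connectivity_rank(network, top_k)
    keep_circ = {n for n, _ in ranked["circRNA"]}
    keep_mrna = {n for n, _ in ranked["mRNA"]}
    rows = []
    for t in triples:
        if t.circ in keep_circ and t.mrna in keep_mrna:
            rows.append({"source": t.circ, "target": t.mirna, "value": t.shared})
            rows.append({"source": t.mirna, "target": t.mrna, "value": t.shared})
    df = pd.DataFrame(rows, columns=["source", "target", "value"])
    return (df.drop_duplicates()
              .sort_values(["source", "target"]).reset_index(drop=True))


def triples_to_frame(triples: list[CeRNATriple]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"circ": t.circ, "mirna": t.mirna, "mrna": t.mrna,
          "rho_mir_circ": t.rho_mir_circ, "rho_mir_mrna": t.rho_mir_mrna,
          "rho_circ_mrna": t.rho_circ_mrna, "shared": t.shared,
          "circ_mirnas": t.circ_mirnas, "mrna_mirnas": t.mrna_mirnas,
          "universe": t.universe, "p": t.p}
         for t in triples])


# re-exported for interface completeness
__all__ = [
    "CorrelationPair", "CeRNATriple", "spearman", "spearman_matrix",
    "screen_negative_pairs", "hypergeom_shared_test", "build_cerna_triples",
    "build_network", "connectivity_rank", "network_edge_table",
    "network_from_edge_table", "sankey_table", "triples_to_frame",
]


def hypergeom_shared_test(m: int, n: int, K: int, N: int) -> float:
    """P(X >= m), X ~ Hypergeometric(N, K, n) — the shared-miRNA test."""
    return hypergeom_sf_shared(m, n, K, N)
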