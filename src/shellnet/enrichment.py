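"""Over-representation analysis of gene sets against term->gene maps.

Terms (GO categories, pathways, or anything else the user supplies as a
two-column table) are tested with the same one-sided hypergeometric kernel
as the shared-miRNA screen. Effect size is the rich factor k/K — the
fraction of a term's genes hit by the query set — which is the x-axis of
the conventional enrichment bubble chart. Significance defaults to raw
p < 0.05 with BH-adjusted FDR reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .stats import bh_adjust, hypergeom_sf_shared

log = logging.getLogger(__name__)


@dataclass
class TermMap:
    """Term id -> member gene ids, with optional names/categories."""

    members: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [t for t, genes in self.members.items() if not genes]
        if empty:
            raise ValueError(f"terms with no member genes: {empty[:5]}")

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.members.values():
            out |= genes
        return out


def load_term_map(path, meta_path=None) -> TermMap:
    """Read a 2-column (term, gene) TSV, plus optional term metadata TSV."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    tab.columns = [c.strip().lower() for c in tab.columns]
    if not {"term", "gene"}.issubset(tab.columns):
        raise ValueError(f"{path}: need columns 'term' and 'gene'")
    members: dict[str, set[str]] = {}
    for _, row in tab.iterrows():
        members.setdefault(str(row["term"]), set()).add(str(row["gene"]))
    names: dict[str, str] = {}
    categories: dict[str, str] = {}
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        meta.columns = [c.strip().lower() for c in meta.columns]
        for _, row in meta.iterrows():
            term = str(row["term"])
            if "name" in meta.columns and not pd.isna(row.get("name")):
                names[term] = str(row["name"])
            if "category" in meta.columns and not pd.isna(row.get("category")):
                categories[term] = str(row["category"])
    return TermMap(members=members, names=names, categories=categories)


def enrich(genes: set[str], terms: TermMap,
           universe: set[str] | None = None) -> pd.DataFrame:
    """Hypergeometric over-representation of ``genes`` in each term.

    The universe defaults to all genes appearing in the term map. Query
    genes outside the universe are dropped with a warning. Returns a frame
    with columns (term, name, category, k, n, K, N, rich_factor, p, FDR),
    one row per term.
    """
    universe = set(universe) if universe is not None else terms.universe
    genes = set(genes)
    outside = genes - universe
    if outside:
        log.warning("%d query gene(s) outside the universe dropped: %s",
                    len(outside), sorted(outside)[:5])
        genes = genes & universe
    N = len(universe)
    n = len(genes)
    rows = []
    for term in sorted(terms.members):
        members = terms.members[term] & universe
        if not members:
            continue
        K = len(members)
        k = len(genes & members)
        p = hypergeom_sf_shared(k, n, K, N)
        rows.append({"term": term,
                     "name": terms.names.get(term, term),
                     "category": terms.categories.get(term, ""),
                     "k": k, "n": n, "K": K, "N": N,
                     "rich_factor": k / K, "p": p})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["FDR"] = bh_adjust(df["p"].to_numpy())
    return df


def top_terms(results: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Top-k terms for the bubble chart: ascending p, ties broken by
    descending rich factor then term id."""
    if results.empty:
        return results
    ranked = results.sort_values(
        ["p", "rich_factor", "term"], ascending=[True, False, True],
        kind="mergesort")
    cols = ["term", "name", "category", "rich_factor", "p", "FDR", "k"]
    return ranked.head(k)[[c for c in cols if c in ranked.columns]].reset_index(drop=True)
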