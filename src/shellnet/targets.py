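"""miRNA target-site prediction: canonical seed matching, plus table import.

The internal predictor implements only the canonical seed-match grammar
(6mer, 7mer-A1, 7mer-m8, 8mer) with no free-energy or conservation scoring:
production predictions from dedicated programs can be imported as TSV
tables instead, and both routes produce the same edge records. U and T are
treated as equivalent on input.

Site grammar, scanning the target 5'->3' for the reverse complement of the
miRNA seed (miRNA positions 2-7, 1-based):
  6mer      seed match only
  7mer-A1   seed match + A in the target opposite miRNA position 1
  7mer-m8   seed match extended to pair miRNA position 8
  8mer      both the m8 pair and the A1 anchor
Only the strongest type is reported per locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_RC = str.maketrans("ACGT", "TGCA")


def _norm(seq: str, what: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"{what}: non-nucleotide characters {sorted(bad)}")
    return s


@dataclass(frozen=True)
class TargetEdge:
    mirna: str
    target: str
    site_type: str | None = None
    position: int | None = None
    provenance: str = "internal"


def find_seed_matches(mirna_id: str, mirna_seq: str,
                      target_id: str, target_seq: str) -> list[TargetEdge]:
    """All canonical seed sites of a miRNA in one target sequence.

    Scans for the reverse complement of the seed (miRNA nt 2-7); each locus
    is upgraded to 7mer/8mer when the m8 pair and/or the A1 anchor are
    present. Positions are 0-based starts of the reported site in the
    target. Requires a miRNA of length >= 8.
    """
    m = _norm(mirna_seq, f"miRNA {mirna_id}")
    t = _norm(target_seq, f"target {target_id}")
    if len(m) < 8:
        raise ValueError(f"miRNA {mirna_id}: length {len(m)} < 8")
    seed6 = m[1:7].translate(_RC)[::-1]     # match for miRNA nt 2-7
    m8_base = m[7].translate(_RC)           # target base pairing miRNA nt 8
    edges: list[TargetEdge] = []
    start = 0
    while True:
        i = t.find(seed6, start)
        if i == -1:
            break
        start = i + 1
        has_m8 = i > 0 and t[i - 1] == m8_base
        has_a1 = i + 6 < len(t) and t[i + 6] == "A"
        if has_m8 and has_a1:
            site, pos = "8mer", i - 1
        elif has_m8:
            site, pos = "7mer-m8", i - 1
        elif has_a1:
            site, pos = "7mer-A1", i
        else:
            site, pos = "6mer", i
        edges.append(TargetEdge(mirna=mirna_id, target=target_id,
                                site_type=site, position=pos,
                                provenance="internal"))
    return edges


def predict_targets(mirnas: dict[str, str],
                    targets: dict[str, str]) -> list[TargetEdge]:
    """Seed-match every miRNA against every target sequence."""
    out: list[TargetEdge] = []
    for mid, mseq in mirnas.items():
        for tid, tseq in targets.items():
            out.extend(find_seed_matches(mid, mseq, tid, tseq))
    return out


def load_target_table(path, known_features: set[str] | None = None) -> list[TargetEdge]:
    """Import a predictor's miRNA->target table (TSV).

    Needs columns ``mirna`` and ``target`` (header names are matched
    case-insensitively; ``site_type`` and ``position`` are optional).
    Duplicate rows collapse to one edge. Malformed rows raise with their
    line numbers; miRNAs absent from ``known_features`` (when given) only
    warn and the edge is kept.
    """
    tab = pd.read_csv(path, sep="\t", dtype=str)
    tab.columns = [c.strip().lower() for c in tab.columns]
    if not {"mirna", "target"}.issubset(tab.columns):
        raise ValueError(f"{path}: need columns 'mirna' and 'target', "
                         f"got {list(tab.columns)}")
    bad_lines = [i + 2 for i, row in tab.iterrows()
                 if pd.isna(row["mirna"]) or pd.isna(row["target"])]
    if bad_lines:
        raise ValueError(f"{path}: malformed rows at lines {bad_lines}")
    edges: dict[tuple, TargetEdge] = {}
    for _, row in tab.iterrows():
        site = row.get("site_type")
        pos = row.get("position")
        edge = TargetEdge(
            mirna=str(row["mirna"]).strip(),
            target=str(row["target"]).strip(),
            site_type=None if pd.isna(site) else str(site),
            position=None if pd.isna(pos) else int(pos),
            provenance="imported",
        )
        edges[(edge.mirna, edge.target, edge.site_type, edge.position)] = edge
    if known_features is not None:
        unknown = {e.mirna for e in edges.values()} - known_features
        if unknown:
            log.warning("imported edges reference miRNAs absent from the "
                        "expression data: %s", sorted(unknown)[:10])
    return list(edges.values())


def combine_edges(a: list[TargetEdge], b: list[TargetEdge],
                  how: str = "union") -> list[TargetEdge]:
    """Combine two predictors' edge sets by (miRNA, target) pair.

    ``how`` is "union" or "intersect" — whichever set policy the analysis
    calls for when two external predictors were run.
    """
    pairs_a = {(e.mirna, e.target) for e in a}
    pairs_b = {(e.mirna, e.target) for e in b}
    if how == "union":
        keep = pairs_a | pairs_b
    elif how == "intersect":
        keep = pairs_a & pairs_b
    else:
        raise ValueError(f"how must be 'union' or 'intersect', got {how!r}")
    seen: dict[tuple[str, str], TargetEdge] = {}
    for e in list(a) + list(b):
        key = (e.mirna, e.target)
        if key in keep and key not in seen:
            seen[key] = e
    return list(seen.values())


def edges_to_map(edges: list[TargetEdge]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for e in edges:
        out.setdefault(e.mirna, set()).add(e.target)
    return out


def edges_to_frame(edges: list[TargetEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"mirna": e.mirna, "target": e.target, "site_type": e.site_type,
          "position": e.position, "provenance": e.provenance}
         for e in edges])
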