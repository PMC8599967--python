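"""ceRNA network assembly by canonical miRNA seed matching.

Binding is predicted by TargetScan-style seed classes rather than any
machine-learned target score: a site is a match of the reverse complement
of miRNA positions 2-8 (7mer-m8), upgraded to 8mer by an A in the target
opposite miRNA position 1, or a 7mer-A1 when only positions 2-7 match but
the A is present.  U and T are interchangeable so DNA- and RNA-alphabet
inputs mix freely; any other character never matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import networkx as nx
import pandas as pd

_RC = str.maketrans("ACGT", "TGCA")


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class SeedSite:
    """A predicted miRNA binding site on a target sequence.

    ``position`` is the 1-based offset of the site's first matched base in
    the target (target read 5'->3').
    """

    site_type: str  # 8mer | 7mer-m8 | 7mer-A1
    position: int


def seed_match(mirna: str, target: str) -> List[SeedSite]:
    """All canonical seed sites of a miRNA (5'->3') on a target sequence.

    Scans the target for the reverse complement of miRNA positions 2-8;
    classifies 8mer when the downstream target base is A (the base paired
    opposite miRNA position 1), 7mer-m8 otherwise, and 7mer-A1 when only
    positions 2-7 match with the A present.
    """
    if len(mirna) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    if not target:
        return []
    m = _normalize(mirna)
    t = _normalize(target)
    seed28 = _rc(m[1:8])  # 7 nt, target 5'->3'
    seed27 = _rc(m[1:7])  # 6 nt
    m8_complement = seed28[0]  # target base pairing miRNA position 8
    valid = set("ACGT")
    sites: List[SeedSite] = []
    for i in range(len(t) - 6):
        window7 = t[i : i + 7]
        if set(window7) <= valid and window7 == seed28:
            has_a1 = i + 7 < len(t) and t[i + 7] == "A"
            sites.append(SeedSite("8mer" if has_a1 else "7mer-m8", i + 1))
            continue
        window6 = t[i : i + 6]
        if (
            set(window6) <= valid
            and window6 == seed27
            and i + 6 < len(t)
            and t[i + 6] == "A"
            # if the upstream base also pairs miRNA position 8 this
            # alignment is the interior of a 7mer-m8/8mer site, not a
            # distinct 7mer-A1
            and (i == 0 or t[i - 1] != m8_complement)
        ):
            sites.append(SeedSite("7mer-A1", i + 1))
    return sites


def build_cerna(
    lnc_circ_seqs: Dict[str, str],
    mirna_seqs: Dict[str, str],
    mrna_utr_seqs: Dict[str, str],
) -> pd.DataFrame:
    """Tripartite lncRNA/circRNA -> miRNA -> mRNA edge list.

    A sponge edge connects a lncRNA/circRNA to a miRNA with >= 1 seed site
    on the lnc/circ sequence; a targeting edge connects a miRNA to an mRNA
    with >= 1 site on its 3'UTR.  Multiple sites on a pair collapse to one
    edge with an ``n_sites`` count.  Columns: source, target, edge_type,
    n_sites, best_site.
    """
    site_rank = {"8mer": 0, "7mer-m8": 1, "7mer-A1": 2}
    rows = []
    for sponge_id in sorted(lnc_circ_seqs):
        for mir_id in sorted(mirna_seqs):
            sites = seed_match(mirna_seqs[mir_id], lnc_circ_seqs[sponge_id])
            if sites:
                best = min(sites, key=lambda s: site_rank[s.site_type])
                rows.append(
                    (sponge_id, mir_id, "sponge", len(sites), best.site_type)
                )
    for mir_id in sorted(mirna_seqs):
        for mrna_id in sorted(mrna_utr_seqs):
            sites = seed_match(mirna_seqs[mir_id], mrna_utr_seqs[mrna_id])
            if sites:
                best = min(sites, key=lambda s: site_rank[s.site_type])
                rows.append(
                    (mir_id, mrna_id, "targeting", len(sites), best.site_type)
                )
    return pd.DataFrame(
        rows, columns=["source", "target", "edge_type", "n_sites", "best_site"]
    )


def cerna_graph(edges: pd.DataFrame) -> nx.DiGraph:
    """Edge-list frame from :func:`build_cerna` as a directed graph with a
    ``tier`` node attribute (sponge / mirna / mrna)."""
    g = nx.DiGraph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.source, row.target, edge_type=row.edge_type,
                   n_sites=row.n_sites)
        if row.edge_type == "sponge":
            g.nodes[row.source]["tier"] = "sponge"
            g.nodes[row.target]["tier"] = "mirna"
        else:
            g.nodes[row.source]["tier"] = "mirna"
            g.nodes[row.target]["tier"] = "mrna"
    return g


def write_sif(edges: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in edges.itertuples(index=False):
            fh.write(f"{row.source}\t{row.edge_type}\t{row.target}\n")
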