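"""Transcriptome-proteome consistency reporting and hypergeometric
over-representation analysis.

Gene identifiers are harmonized by exact symbol match after uppercasing;
no alias resolution is attempted.  Over-representation p-values are the
hypergeometric upper tail P[X >= k] with Benjamini-Hochberg q-values
across the collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def _norm(genes: Iterable[str]) -> Set[str]:
    return {str(g).upper() for g in genes}


@dataclass
class ConsistencyReport:
    """Cross-layer overlaps with per-gene direction concordance.

    ``mrna_protein`` lists genes differentially expressed in both the mRNA
    and protein layers; ``concordant`` flags whether the log2 fold changes
    share a sign.  ``lnc_targets_protein`` / ``circ_origin_protein`` are
    the cis-target and origin-gene overlaps with the DE proteins.
    """

    mrna_protein: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene", "lfc_mrna", "lfc_protein", "concordant"]
        )
    )
    lnc_targets_protein: List[str] = field(default_factory=list)
    circ_origin_protein: List[str] = field(default_factory=list)

    @property
    def mrna_protein_genes(self) -> List[str]:
        return list(self.mrna_protein["gene"])


def overlap_sets(
    de_mrna: pd.DataFrame,
    de_protein: pd.DataFrame,
    links: Optional[pd.DataFrame] = None,
) -> ConsistencyReport:
    """Intersect the DE layers and the link targets with the DE proteins.

    ``de_mrna`` / ``de_protein`` are the DE tables (indexed by feature id,
    with ``is_de`` and ``log2FoldChange``); ``links`` is the combined link
    table with ``link_type`` in {cis_target, origin} and ``target_gene``.
    Empty inputs yield an empty report.
    """
    def _de_map(table: pd.DataFrame) -> Dict[str, float]:
        if table is None or table.empty:
            return {}
        de = table[table["is_de"]]
        return {
            str(idx).upper(): float(lfc)
            for idx, lfc in zip(de.index, de["log2FoldChange"])
        }

    mrna = _de_map(de_mrna)
    prot = _de_map(de_protein)
    shared = sorted(set(mrna) & set(prot))
    mrna_protein = pd.DataFrame(
        {
            "gene": shared,
            "lfc_mrna": [mrna[g] for g in shared],
            "lfc_protein": [prot[g] for g in shared],
            "concordant": [mrna[g] * prot[g] > 0 for g in shared],
        }
    )
    lnc_overlap: List[str] = []
    circ_overlap: List[str] = []
    if links is not None and not links.empty:
        cis = _norm(links.loc[links["link_type"] == "cis_target", "target_gene"])
        origin = _norm(links.loc[links["link_type"] == "origin", "target_gene"])
        lnc_overlap = sorted(cis & set(prot))
        circ_overlap = sorted(origin & set(prot))
    return ConsistencyReport(
        mrna_protein=mrna_protein,
        lnc_targets_protein=lnc_overlap,
        circ_origin_protein=circ_overlap,
    )


def read_gmt(path: str | Path) -> Dict[str, List[str]]:
    """GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = fields[2:]
    return sets


def hypergeom_enrich(
    query: Iterable[str],
    collection: Dict[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Over-representation of the query in each gene set.

    Query and every set are intersected with the universe first.  For a
    universe of N genes, a set of K and a query of n sharing k genes,
    p = P[X >= k] for X ~ Hypergeometric(N, K, n).  Sets empty after
    intersection are skipped.  Returns a frame sorted by p with columns
    set_name, k, K, n, N, pvalue, qvalue.
    """
    uni = _norm(universe)
    if not uni:
        raise ValueError("empty universe")
    q = _norm(query) & uni
    N, n = len(uni), len(q)
    rows = []
    for name, members in collection.items():
        members_u = _norm(members) & uni
        K = len(members_u)
        if K == 0:
            continue
        k = len(members_u & q)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "pvalue"])
    if df.empty:
        df["qvalue"] = pd.Series(dtype=float)
        return df
    df["qvalue"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    return df.sort_values(["pvalue", "set_name"], kind="mergesort").reset_index(
        drop=True
    )
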