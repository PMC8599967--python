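"""Cis-target and origin-gene assignment by interval logic.

A lncRNA is linked to every protein-coding gene whose genomic span lies
within a +-window (default 1 kb) of the lncRNA's own span, strand-ignored;
a circRNA is linked to every gene with at least 1 bp of exonic overlap
with the circle interval (one circle spanning exons of two genes yields
two links).
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import BackspliceJunction, TranscriptModel

LINK_COLUMNS = ["source_id", "target_gene", "link_type", "distance_bp"]


def gene_spans(
    transcripts: Sequence[TranscriptModel],
) -> Dict[str, Tuple[str, int, int]]:
    """Per gene, the genomic span of its longest (spliced) transcript."""
    best: Dict[str, TranscriptModel] = {}
    for t in transcripts:
        cur = best.get(t.gene_id)
        if cur is None or t.length > cur.length or (
            t.length == cur.length and t.transcript_id < cur.transcript_id
        ):
            best[t.gene_id] = t
    return {
        gid: (t.chrom, t.span[0], t.span[1]) for gid, t in best.items()
    }


def _span_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two 1-based inclusive intervals; 0 when they
    overlap or abut."""
    return max(0, max(b_start - a_end, a_start - b_end) - 1)


def cis_targets(
    lncrnas: Sequence[TranscriptModel],
    coding: Sequence[TranscriptModel],
    window: int = 1000,
) -> pd.DataFrame:
    """Link each lncRNA to coding genes within ``window`` bp of its span.

    The gap between genomic spans must be <= window (inclusive; overlap
    counts as 0), same chromosome, either strand.  Returns a sorted frame
    with columns source_id, target_gene, link_type, distance_bp.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    spans = gene_spans(coding)
    by_chrom: Dict[str, List[Tuple[str, int, int]]] = {}
    for gid, (chrom, s, e) in spans.items():
        by_chrom.setdefault(chrom, []).append((gid, s, e))
    rows = []
    for lnc in lncrnas:
        genes = by_chrom.get(lnc.chrom)
        if not genes:
            continue
        ls, le = lnc.span
        gids = np.array([g[0] for g in genes])
        starts = np.array([g[1] for g in genes])
        ends = np.array([g[2] for g in genes])
        gaps = np.maximum(
            0, np.maximum(starts - le, ls - ends) - 1
        )
        hit = gaps <= window
        for gid, gap in zip(gids[hit], gaps[hit]):
            rows.append((lnc.transcript_id, str(gid), "cis_target", int(gap)))
    return (
        pd.DataFrame(rows, columns=LINK_COLUMNS)
        .sort_values(["source_id", "target_gene"], kind="mergesort")
        .reset_index(drop=True)
    )


def origin_genes(
    junctions: Sequence[BackspliceJunction],
    coding: Sequence[TranscriptModel],
    stranded: bool = False,
) -> pd.DataFrame:
    """Link each circRNA to genes whose exons overlap the circle interval.

    Overlap of >= 1 bp between [acceptor, donor] and any exon of any
    transcript of the gene creates a link; strand is ignored unless
    ``stranded`` is set.  Distance is 0 by definition (overlap links).
    """
    rows = []
    for j in junctions:
        linked = set()
        for t in coding:
            if t.chrom != j.chrom or t.gene_id in linked:
                continue
            if stranded and t.strand != j.strand:
                continue
            for s, e in t.exons:
                if s <= j.donor and j.acceptor <= e:
                    linked.add(t.gene_id)
                    break
        for gid in sorted(linked):
            rows.append((j.name, gid, "origin", 0))
    return (
        pd.DataFrame(rows, columns=LINK_COLUMNS)
        .sort_values(["source_id", "target_gene"], kind="mergesort")
        .reset_index(drop=True)
    )
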