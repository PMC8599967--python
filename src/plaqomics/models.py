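"""Core genomic feature models and their text-format round trips.

Coordinates follow the GTF convention externally (1-based, inclusive) and
are stored that way on the models; helper properties expose 0-based slices
where sequence access is needed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple


@dataclass
class TranscriptModel:
    """Stranded exon-chain transcript model.

    ``exons`` are 1-based inclusive ``(start, end)`` intervals, sorted and
    non-overlapping.  ``coverage`` mirrors the assembler's per-base read
    depth attribute (``cov`` in GTF output).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    biotype: str = "protein_coding"
    coverage: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"overlapping exons in {self.transcript_id}: "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        for s, e in exons:
            if s < 1 or e < s:
                raise ValueError(f"invalid exon ({s},{e}) in {self.transcript_id}")
        self.exons = exons

    @property
    def length(self) -> int:
        """Spliced transcript length (sum of exon lengths)."""
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> Tuple[int, int]:
        """Genomic span (first exon start, last exon end), 1-based inclusive."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> List[Tuple[int, int]]:
        """1-based inclusive intron intervals between consecutive exons."""
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def spliced_sequence(self, genome) -> str:
        """Exon-concatenated sequence on the forward strand; reverse
        complemented for minus-strand transcripts."""
        from .genome import reverse_complement

        seq = "".join(
            genome.slice(self.chrom, s - 1, e) for s, e in self.exons
        )
        return reverse_complement(seq) if self.strand == "-" else seq


@dataclass(frozen=True)
class BackspliceJunction:
    """A back-splice (head-to-tail) junction defining a circRNA.

    ``acceptor`` is the leftmost genomic base of the circle and ``donor``
    the rightmost, both 1-based inclusive, so ``acceptor < donor`` always.
    ``signal_ok`` records whether the flanking genomic dinucleotides match
    the canonical splice signal (AG immediately upstream of the acceptor,
    GT immediately downstream of the donor).
    """

    chrom: str
    acceptor: int
    donor: int
    strand: str
    support: int = 1
    signal_ok: bool = False

    def __post_init__(self) -> None:
        if not self.acceptor < self.donor:
            raise ValueError(
                f"acceptor must precede donor ({self.acceptor} >= {self.donor})"
            )
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def span(self) -> int:
        return self.donor - self.acceptor + 1

    @property
    def key(self) -> Tuple[str, int, int, str]:
        return (self.chrom, self.acceptor, self.donor, self.strand)

    @property
    def name(self) -> str:
        return f"circ:{self.chrom}:{self.acceptor}-{self.donor}:{self.strand}"


# --------------------------------------------------------------------- GTF

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attributes(attr_field: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


class GtfParseError(ValueError):
    """Malformed GTF input; carries the 1-based offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"GTF line {line_number}: {message}")
        self.line_number = line_number


def read_gtf(path: str | Path) -> List[TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    Only ``exon`` lines are consumed; transcripts are reconstructed by
    grouping on ``transcript_id``.  Raises :class:`GtfParseError` naming the
    offending line on malformed input.
    """
    exons: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Dict[str, str]] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}", lineno
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise GtfParseError(
                    f"non-integer coordinates {start!r}/{end!r}", lineno
                ) from None
            if strand not in "+-":
                raise GtfParseError(f"invalid strand {strand!r}", lineno)
            attr = _parse_attributes(attrs)
            tid = attr.get("transcript_id")
            if not tid:
                raise GtfParseError("missing transcript_id attribute", lineno)
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
                meta[tid] = {
                    "gene_id": attr.get("gene_id", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": attr.get("gene_biotype", attr.get("biotype", "")),
                    "cov": attr.get("cov", "0"),
                }
            exons[tid].append((start_i, end_i))
    return [
        TranscriptModel(
            transcript_id=tid,
            gene_id=meta[tid]["gene_id"],
            chrom=meta[tid]["chrom"],
            strand=meta[tid]["strand"],
            exons=exons[tid],
            biotype=meta[tid]["biotype"] or "unknown",
            coverage=float(meta[tid]["cov"]),
        )
        for tid in order
    ]


def write_gtf(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GTF (transcript + exon lines, 1-based inclusive)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_biotype "{t.biotype}"; cov "{t.coverage:.6f}";'
            )
            span = t.span
            fh.write(
                "\t".join(
                    [t.chrom, "plaqomics", "transcript", str(span[0]), str(span[1]),
                     ".", t.strand, ".", attrs]
                )
                + "\n"
            )
            for i, (s, e) in enumerate(t.exons, start=1):
                fh.write(
                    "\t".join(
                        [t.chrom, "plaqomics", "exon", str(s), str(e),
                         ".", t.strand, ".", attrs + f' exon_number "{i}";']
                    )
                    + "\n"
                )


# --------------------------------------------------------------------- BED

def write_junctions_bed(
    junctions: Sequence[BackspliceJunction], path: str | Path
) -> None:
    """Write junctions as BED6: chromStart = acceptor-1 (0-based), chromEnd =
    donor, score = supporting read count."""
    with open(path, "w") as fh:
        for j in sorted(junctions, key=lambda j: j.key):
            fh.write(
                f"{j.chrom}\t{j.acceptor - 1}\t{j.donor}\t{j.name}\t"
                f"{j.support}\t{j.strand}\n"
            )


def read_junctions_bed(path: str | Path) -> List[BackspliceJunction]:
    out: List[BackspliceJunction] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, _name, score, strand = line.split("\t")[:6]
            out.append(
                BackspliceJunction(
                    chrom=chrom,
                    acceptor=int(start) + 1,
                    donor=int(end),
                    strand=strand.strip(),
                    support=int(score),
                )
            )
    return out
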