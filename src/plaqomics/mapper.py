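"""Exact k-mer indexed short-read placement on small genomes.

This is the linear-read triage stage: reads that place contiguously on the
genome (either strand) are "mapped"; reads with no contiguous placement are
routed to back-splice junction candidacy.  It deliberately does no spliced,
gapped or quality-aware alignment — on the small synthetic genomes this
toolkit targets, exact seeding plus verification is complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

from .genome import GenomeRef, reverse_complement


@dataclass(frozen=True)
class AnchorHit:
    """A genomic placement of a short sequence.

    ``pos`` is the 0-based forward-strand coordinate of the leftmost base of
    the matched window regardless of strand.  ``unique`` is true iff the
    sequence has exactly one placement genome-wide.
    """

    chrom: str
    pos: int
    strand: str
    unique: bool = True


class KmerIndex:
    """Hash index of every genomic k-mer on both strands.

    Minus-strand entries map the reverse complement of a forward window to
    the forward coordinate of that window's start.  Windows containing
    ambiguous bases are not indexed; N never matches anything.
    """

    def __init__(self, genome: GenomeRef, k: int = 20):
        shortest = min(len(s) for s in genome.sequences.values())
        if not 1 <= k <= shortest:
            raise ValueError(
                f"k={k} must be between 1 and the shortest chromosome "
                f"length ({shortest})"
            )
        self.k = k
        self.genome = genome
        self._index: Dict[str, List[Tuple[str, int, str]]] = {}
        for chrom, seq in genome.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((chrom, pos, "+"))
                self._index.setdefault(reverse_complement(kmer), []).append(
                    (chrom, pos, "-")
                )

    def lookup(self, kmer: str) -> List[AnchorHit]:
        """All genomic placements of an exact k-length sequence."""
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != index k {self.k}")
        raw = self._index.get(kmer, [])
        unique = len(raw) == 1
        return [AnchorHit(c, p, s, unique) for c, p, s in raw]


def build_index(genome: GenomeRef, k: int = 20) -> KmerIndex:
    """Build a both-strand k-mer index over the genome (k defaults to the
    20 bp anchor length)."""
    return KmerIndex(genome, k)


def _mismatches(a: str, b: str, limit: int) -> int:
    """Hamming distance with N counting as mismatch; early exit past limit."""
    n = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            n += 1
            if n > limit:
                return n
    return n


def map_linear(
    index: KmerIndex, read: str, max_mismatches: int = 0
) -> List[AnchorHit]:
    """Place a read contiguously on the genome via k-mer seeding + extension.

    Returns every placement (both strands) with at most ``max_mismatches``
    substitutions; an empty list means the read is unmapped and a candidate
    for back-splice calling.  Seeds are taken at non-overlapping offsets so
    the search is complete whenever ``max_mismatches`` is smaller than the
    number of seeds (always true at the default of 0).
    """
    if not read:
        raise ValueError("empty read")
    read = read.upper()
    L = len(read)
    k = index.k
    if L < k:
        return []
    genome = index.genome
    offsets = list(range(0, L - k + 1, k))
    if offsets[-1] != L - k:
        offsets.append(L - k)
    placements = set()
    for off in offsets:
        for hit in index.lookup(read[off : off + k]):
            if hit.strand == "+":
                start = hit.pos - off
            else:
                # seed matched the minus strand; the full-read window starts
                # at the seed window's end minus the read suffix length
                start = hit.pos + k - (L - off)
            if start < 0 or start + L > genome.length(hit.chrom):
                continue
            window = genome.slice(hit.chrom, start, start + L)
            target = read if hit.strand == "+" else reverse_complement(read)
            if _mismatches(window, target, max_mismatches) <= max_mismatches:
                placements.add((hit.chrom, start, hit.strand))
    hits = sorted(placements)
    unique = len(hits) == 1
    return [AnchorHit(c, p, s, unique) for c, p, s in hits]
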