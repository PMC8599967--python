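"""Reference genome container with FASTA round-trip.

A :class:`GenomeRef` is a thin ordered mapping from chromosome name to an
uppercase DNA string.  Sequences are kept as plain Python strings: the
genomes this toolkit operates on are small (tens to hundreds of kilobases),
and string slicing is the dominant access pattern for anchor extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRef:
    """Named chromosome sequences.

    Parameters
    ----------
    sequences
        Mapping of chromosome name to uppercase A/C/G/T(/N) sequence.
    """

    sequences: Dict[str, str] = field(default_factory=dict)

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def items(self) -> Iterator[Tuple[str, str]]:
        return iter(self.sequences.items())

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def slice(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open slice of a chromosome."""
        return self.sequences[chrom][start:end]

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeRef":
        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")
        }
        if not seqs:
            raise ValueError(f"no sequences found in FASTA {path}")
        return cls(seqs)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")
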