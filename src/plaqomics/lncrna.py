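"""lncRNA class-code assignment and the expressed-lncRNA filter cascade.

Class codes mirror the assembler-vs-reference comparison vocabulary:
``x`` antisense exonic overlap, ``u`` intergenic, ``i`` contained in a
single reference intron, ``other`` anything else (notably same-strand
exonic overlap, which disqualifies a transcript as a novel lncRNA).

The filter keeps transcripts with spliced length > 200 nt, at least two
exons, class code in {x, u, i} and assembly coverage > 3 (strict
inequalities for length and coverage).
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .models import TranscriptModel

ADMISSIBLE_CODES = ("x", "u", "i")


def _intervals_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _exonic_overlap(t: TranscriptModel, ref: TranscriptModel) -> bool:
    for e in t.exons:
        for r in ref.exons:
            if _intervals_overlap(e, r):
                return True
    return False


def assign_class_code(
    transcript: TranscriptModel, reference: Sequence[TranscriptModel]
) -> str:
    """Assign x/u/i/other relative to a reference annotation.

    Precedence: same-strand exonic overlap forces ``other``; otherwise
    antisense exonic overlap gives ``x``; otherwise containment within a
    single intron of one reference transcript gives ``i``; a transcript
    with no overlap of any reference gene span is ``u``; anything else
    (span overlap without exonic overlap or intron containment) is
    ``other``.  A transcript on a chromosome absent from the reference is
    ``u`` with a warning.
    """
    same_chrom = [r for r in reference if r.chrom == transcript.chrom]
    if not same_chrom:
        warnings.warn(
            f"{transcript.transcript_id}: chromosome {transcript.chrom} absent "
            "from reference; classifying as intergenic",
            RuntimeWarning,
        )
        return "u"
    span = transcript.span
    span_overlaps = [r for r in same_chrom if _intervals_overlap(span, r.span)]
    if not span_overlaps:
        return "u"
    for r in span_overlaps:
        if r.strand == transcript.strand and _exonic_overlap(transcript, r):
            return "other"
    for r in span_overlaps:
        if r.strand != transcript.strand and _exonic_overlap(transcript, r):
            return "x"
    for r in span_overlaps:
        if _exonic_overlap(transcript, r):
            continue
        for intron in r.introns:
            if intron[0] <= span[0] and span[1] <= intron[1]:
                return "i"
    return "other"


def classify_all(
    transcripts: Sequence[TranscriptModel], reference: Sequence[TranscriptModel]
) -> Dict[str, str]:
    """Class code per transcript id."""
    return {
        t.transcript_id: assign_class_code(t, reference) for t in transcripts
    }


def filter_lncrna(
    transcripts: Sequence[TranscriptModel],
    codes: Dict[str, str],
    min_length: int = 200,
    min_exons: int = 2,
    min_coverage: float = 3.0,
) -> List[str]:
    """Transcript ids passing the expressed-lncRNA cascade.

    Keeps a transcript iff length > min_length (strict), exon count >=
    min_exons, class code in {x, u, i} and coverage > min_coverage
    (strict).
    """
    kept = []
    for t in transcripts:
        code = codes.get(t.transcript_id)
        if (
            t.length > min_length
            and t.n_exons >= min_exons
            and code in ADMISSIBLE_CODES
            and t.coverage > min_coverage
        ):
            kept.append(t.transcript_id)
    return kept


def classification_table(
    transcripts: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
    min_length: int = 200,
    min_exons: int = 2,
    min_coverage: float = 3.0,
) -> pd.DataFrame:
    """Per-transcript classification and filter verdicts as a data frame
    (columns transcript_id, code, length, n_exons, coverage, kept)."""
    codes = classify_all(transcripts, reference)
    kept = set(
        filter_lncrna(transcripts, codes, min_length, min_exons, min_coverage)
    )
    return pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in transcripts],
            "code": [codes[t.transcript_id] for t in transcripts],
            "length": [t.length for t in transcripts],
            "n_exons": [t.n_exons for t in transcripts],
            "coverage": [t.coverage for t in transcripts],
            "kept": [t.transcript_id in kept for t in transcripts],
        }
    )
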