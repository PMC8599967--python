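"""Anchor-based back-splice junction calling and circRNA quantification.

A read that fails contiguous placement is split into a 5' and a 3' terminal
anchor (20 bp each by default).  If both anchors place uniquely on the same
chromosome and strand but in *reversed* genomic order — the 5' anchor
downstream of the 3' anchor — the read spans a head-to-tail (back-splice)
junction.  Both anchors are then extended toward the read interior against
the genome to localize the breakpoint; among the splits that explain the
whole read, the one whose genomic flanks carry the canonical splice signal
(AG immediately upstream of the circle start, GT immediately downstream of
its end) is preferred, with the smallest 5'-anchor extension as the
deterministic tie-break.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .genome import GenomeRef, reverse_complement
from .mapper import KmerIndex, map_linear
from .models import BackspliceJunction

#: rejection reason codes
TOO_SHORT = "too-short"
UNMAPPED_ANCHOR = "unmapped-anchor"
AMBIGUOUS = "ambiguous"
DISCORDANT = "discordant"
COLLINEAR = "collinear"
TOO_LONG = "too-long"
NO_EXTENSION = "no-extension"
NO_SIGNAL = "no-signal"


@dataclass(frozen=True)
class Rejection:
    """A read rejected by the junction caller, with the reason code."""

    reason: str


@dataclass
class CircParams:
    """Caller parameters.

    ``signal`` selects the expected flanking dinucleotides: ``"AG-GT"``
    (acceptor-side AG upstream, donor-side GT downstream — the canonical
    GT-AG intron written acceptor-first), ``"GT-AG"`` (swapped), or
    ``"off"`` (no signal check).  With ``require_signal`` true, reads with
    no signal-consistent breakpoint are rejected instead of being emitted
    with ``signal_ok=False``.
    """

    anchor_len: int = 20
    max_span: int = 100_000
    signal: str = "AG-GT"
    require_signal: bool = True
    min_support: int = 1

    def __post_init__(self) -> None:
        if self.signal not in ("AG-GT", "GT-AG", "off"):
            raise ValueError(f"unknown signal mode {self.signal!r}")

    @property
    def flanks(self) -> Optional[Tuple[str, str]]:
        if self.signal == "AG-GT":
            return ("AG", "GT")
        if self.signal == "GT-AG":
            return ("GT", "AG")
        return None


def extract_anchors(read: str, anchor_len: int = 20) -> Tuple[str, str]:
    """First and last ``anchor_len`` bases of the read.

    Raises ``ValueError`` for reads shorter than two anchors; the caller
    maps this to the ``too-short`` rejection code.
    """
    if len(read) < 2 * anchor_len:
        raise ValueError(
            f"read of {len(read)} nt shorter than two {anchor_len} bp anchors"
        )
    return read[:anchor_len], read[-anchor_len:]


def _extend_forward(read: str, genome_seq: str, p5: int, k: int) -> int:
    """Longest prefix of the read matching the genome starting at p5."""
    L, n = len(read), len(genome_seq)
    i = k
    while i < L and p5 + i < n and read[i] == genome_seq[p5 + i]:
        i += 1
    return i


def _extend_backward(read: str, genome_seq: str, end3: int, k: int) -> int:
    """Longest suffix of the read matching the genome ending at end3."""
    L = len(read)
    j = k
    while j < L and end3 - 1 - j >= 0 and read[L - 1 - j] == genome_seq[end3 - 1 - j]:
        j += 1
    return j


def call_backsplice(
    index: KmerIndex,
    genome: GenomeRef,
    read: str,
    params: Optional[CircParams] = None,
) -> Union[BackspliceJunction, Rejection]:
    """Call a back-splice junction from a linearly unmappable read.

    Returns a :class:`BackspliceJunction` (support 1) or a
    :class:`Rejection` carrying the reason code.
    """
    params = params or CircParams()
    read = read.upper()
    k = params.anchor_len
    try:
        a5, a3 = extract_anchors(read, k)
    except ValueError:
        return Rejection(TOO_SHORT)
    if index.k != k:
        raise ValueError(f"index k={index.k} does not match anchor_len={k}")

    hits5 = index.lookup(a5)
    hits3 = index.lookup(a3)
    if not hits5 or not hits3:
        return Rejection(UNMAPPED_ANCHOR)
    if len(hits5) > 1 or len(hits3) > 1:
        return Rejection(AMBIGUOUS)
    h5, h3 = hits5[0], hits3[0]
    if h5.chrom != h3.chrom or h5.strand != h3.strand:
        return Rejection(DISCORDANT)

    if h5.strand == "-":
        # equivalent forward problem on the reverse-complemented read; the
        # genomic junction coordinates are strand-invariant
        result = call_backsplice(index, genome, reverse_complement(read), params)
        if isinstance(result, Rejection):
            return result
        return BackspliceJunction(
            chrom=result.chrom, acceptor=result.acceptor, donor=result.donor,
            strand="-", support=1, signal_ok=result.signal_ok,
        )

    p5, p3 = h5.pos, h3.pos
    if p5 <= p3:
        return Rejection(COLLINEAR)

    seq = genome[h5.chrom]
    L = len(read)
    s_max = _extend_forward(read, seq, p5, k)
    t_max = _extend_backward(read, seq, p3 + k, k)
    lo = max(1, L - t_max)
    hi = min(L - 1, s_max)
    candidates: List[Tuple[int, int, int, bool]] = []
    flanks = params.flanks
    for s in range(lo, hi + 1):
        acceptor0 = p3 + k - (L - s)
        donor0 = p5 + s - 1
        if acceptor0 < 0 or acceptor0 >= donor0:
            continue
        if flanks is None:
            ok = False
        else:
            left = seq[max(0, acceptor0 - 2) : acceptor0]
            right = seq[donor0 + 1 : donor0 + 3]
            ok = left == flanks[0] and right == flanks[1]
        candidates.append((s, acceptor0, donor0, ok))
    if not candidates:
        return Rejection(NO_EXTENSION)

    with_signal = [c for c in candidates if c[3]]
    if with_signal:
        s, acceptor0, donor0, ok = with_signal[0]  # smallest 5' extension
    elif flanks is not None and params.require_signal:
        return Rejection(NO_SIGNAL)
    else:
        s, acceptor0, donor0, ok = candidates[0]

    if donor0 - acceptor0 + 1 > params.max_span:
        return Rejection(TOO_LONG)
    return BackspliceJunction(
        chrom=h5.chrom, acceptor=acceptor0 + 1, donor=donor0 + 1,
        strand="+", support=1, signal_ok=ok,
    )


def collapse_and_count(
    calls: Iterable[Union[BackspliceJunction, Rejection]],
    min_support: int = 1,
) -> List[BackspliceJunction]:
    """Merge identical junction calls, count supporting reads, and drop
    junctions below the support threshold."""
    counter: Counter = Counter()
    signal: Dict[Tuple, bool] = {}
    for call in calls:
        if isinstance(call, Rejection):
            continue
        counter[call.key] += call.support
        signal[call.key] = signal.get(call.key, False) or call.signal_ok
    out = [
        BackspliceJunction(
            chrom=c, acceptor=a, donor=d, strand=st,
            support=n, signal_ok=signal[(c, a, d, st)],
        )
        for (c, a, d, st), n in counter.items()
        if n >= min_support
    ]
    return sorted(out, key=lambda j: j.key)


def tpm_from_supports(supports, lengths) -> "pd.Series":
    """TPM from raw support and effective-length vectors.

    rate_i = support_i / (length_i / 1000); tpm_i = rate_i / sum(rate) * 1e6;
    an all-zero support vector yields all-zero TPM (no division by zero).
    """
    supports = pd.Series(supports, dtype=float)
    lengths = pd.Series(lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    if (supports < 0).any():
        raise ValueError("supports must be non-negative")
    rate = supports / (lengths / 1000.0)
    total = rate.sum()
    if total == 0:
        return rate * 0.0
    return rate / total * 1e6


def tpm_quantify(
    junctions: Sequence[BackspliceJunction],
    effective_lengths: Optional[Dict[str, float]] = None,
    junction_length_mode: bool = False,
) -> pd.DataFrame:
    """Transcripts-per-million over junction read support.

    rate_i = support_i / (length_i / 1000); tpm_i = rate_i / sum(rate) * 1e6.
    The effective length defaults to the genomic span of the circle; with
    ``junction_length_mode`` every length is 1 so TPM is proportional to
    raw junction support.  All-zero support yields all-zero TPM.
    """
    rows = []
    for j in junctions:
        if junction_length_mode:
            length = 1.0
        elif effective_lengths is not None:
            length = float(effective_lengths[j.name])
        else:
            length = float(j.span)
        if length <= 0:
            raise ValueError(f"non-positive effective length for {j.name}")
        rows.append((j.name, j.support, length, j.signal_ok))
    df = pd.DataFrame(
        rows, columns=["junction_id", "support", "effective_length", "signal_ok"]
    )
    if df.empty:
        df["tpm"] = pd.Series(dtype=float)
        return df
    df["tpm"] = tpm_from_supports(df["support"], df["effective_length"]).to_numpy()
    return df


def detect_circrnas(
    genome: GenomeRef,
    reads: Sequence,
    params: Optional[CircParams] = None,
    index: Optional[KmerIndex] = None,
) -> Tuple[List[BackspliceJunction], Dict[str, int]]:
    """Full caller: linear triage, per-read junction calling, collapsing.

    ``reads`` are objects with ``read_id`` and ``sequence`` attributes (or
    plain strings).  Returns collapsed junctions plus a tally of outcomes
    ({"mapped": .., "backsplice": .., <rejection reasons>: ..}).
    """
    params = params or CircParams()
    if index is None:
        index = KmerIndex(genome, params.anchor_len)
    tally: Counter = Counter()
    calls: List[Union[BackspliceJunction, Rejection]] = []
    for r in reads:
        seq = r if isinstance(r, str) else r.sequence
        if map_linear(index, seq):
            tally["mapped"] += 1
            continue
        result = call_backsplice(index, genome, seq, params)
        if isinstance(result, Rejection):
            tally[result.reason] += 1
        else:
            tally["backsplice"] += 1
            calls.append(result)
    junctions = collapse_and_count(calls, params.min_support)
    return junctions, dict(tally)
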