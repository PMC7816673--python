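"""Genome-terminus calling from read-end pileups.

Terminal-complete dsRNA sequencing preserves genome ends through adapter
ligation, so reads pile up with alignment boundaries exactly at the true
5'/3' termini.  A contig extremity is called a genome terminus when strictly
more than ``min_support`` reads have their alignment boundary at that
extremity, or (3' side only) when the contig ends in a polyA run.  A contig
with termini called at both ends is classified full-length; otherwise
partial.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadAlignment:
    """One read aligned to one contig (0-based half-open interval)."""

    read_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"read {self.read_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id!r}: strand must be '+' or '-'")


@dataclass(frozen=True)
class TerminusCall:
    """Evidence-backed call of a 5' or 3' genome end at a contig extremity.

    ``support`` counts reads whose alignment boundary coincides with the
    extremity; ``polya`` records 3' polyA evidence; ``called`` is the verdict.
    """

    contig_id: str
    side: str  # "5p" | "3p"
    coordinate: int  # position of the extreme base (0 or len-1)
    support: int
    polya: bool
    called: bool


@dataclass
class Contig:
    """A contig awaiting terminus calling."""

    contig_id: str
    sequence: str
    host_strain: str = ""


@dataclass
class GenomeSegment:
    """A contig with terminus status and completeness label."""

    segment_id: str
    host_strain: str
    sequence: str
    has_5p_terminus: bool = False
    has_3p_terminus: bool = False
    polya_3p: bool = False
    completeness: str = "partial"  # "full_length" | "partial"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"segment {self.segment_id!r}: empty sequence")

    @property
    def is_full_length(self) -> bool:
        return self.completeness == "full_length"


def pileup_read_ends(
    alignments: list[ReadAlignment], contig_id: str, contig_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Count alignment starts and ends per contig position.

    Returns ``(start_counts, end_counts)``, both of length ``contig_length``:
    ``start_counts[i]`` is the number of alignments starting at position
    ``i``; ``end_counts[i]`` the number whose last aligned base is ``i``.
    Each vector sums to the number of alignments on the contig.
    """
    starts = np.zeros(contig_length, dtype=np.int64)
    ends = np.zeros(contig_length, dtype=np.int64)
    for aln in alignments:
        if aln.contig_id != contig_id:
            raise ValueError(
                f"read {aln.read_id!r} aligns to {aln.contig_id!r}, not {contig_id!r}"
            )
        if aln.end > contig_length:
            raise ValueError(
                f"read {aln.read_id!r} extends past contig end "
                f"({aln.end} > {contig_length})"
            )
        starts[aln.start] += 1
        ends[aln.end - 1] += 1
    return starts, ends


def _polya_tail(sequence: str, polya_min: int) -> bool:
    return len(sequence) >= polya_min and sequence.endswith("A" * polya_min)


def call_terminus(
    boundary_counts: np.ndarray,
    contig_sequence: str,
    side: str,
    contig_id: str = "",
    min_support: int = 10,
    polya_min: int = 8,
) -> TerminusCall:
    """Apply the terminus rule at one contig extremity.

    ``boundary_counts`` is the start-count vector for ``side='5p'`` or the
    end-count vector for ``side='3p'`` (as produced by
    :func:`pileup_read_ends`).  The call is positive iff the boundary count at
    the extremity is STRICTLY greater than ``min_support`` ("more than ten
    reads" under the default), or, on the 3' side, the contig ends in at
    least ``polya_min`` consecutive A.

    Internal boundary peaks exceeding ``min_support`` are logged as warnings
    (possible mis-assembly) but never produce calls.
    """
    if side not in ("5p", "3p"):
        raise ValueError(f"side must be '5p' or '3p', got {side!r}")
    if not contig_sequence:
        raise ValueError(f"contig {contig_id!r}: empty sequence")
    if min_support < 0:
        raise ValueError("min_support must be >= 0")
    n = len(contig_sequence)
    counts = np.asarray(boundary_counts)
    if counts.shape[0] != n:
        raise ValueError(
            f"contig {contig_id!r}: boundary counts length {counts.shape[0]} "
            f"!= contig length {n}"
        )

    coordinate = 0 if side == "5p" else n - 1
    support = int(counts[coordinate])
    polya = side == "3p" and _polya_tail(contig_sequence, polya_min)
    called = support > min_support or polya

    interior = counts[1:-1] if n > 2 else counts[:0]
    peaks = np.nonzero(interior > min_support)[0]
    if peaks.size:
        logger.warning(
            "contig %s: %d internal %s-boundary peak(s) above min_support "
            "(possible mis-assembly), first at position %d",
            contig_id, peaks.size, side, int(peaks[0]) + 1,
        )

    return TerminusCall(
        contig_id=contig_id,
        side=side,
        coordinate=coordinate,
        support=support,
        polya=polya,
        called=called,
    )


def classify_completeness(
    contig: Contig, call_5p: TerminusCall, call_3p: TerminusCall
) -> GenomeSegment:
    """Label a contig full-length iff termini were called at both ends."""
    for call in (call_5p, call_3p):
        if call.contig_id != contig.contig_id:
            raise ValueError(
                f"terminus call for {call.contig_id!r} does not match contig "
                f"{contig.contig_id!r}"
            )
    if call_5p.side != "5p" or call_3p.side != "3p":
        raise ValueError("calls must be passed as (5p, 3p)")
    full = call_5p.called and call_3p.called
    return GenomeSegment(
        segment_id=contig.contig_id,
        host_strain=contig.host_strain,
        sequence=contig.sequence,
        has_5p_terminus=call_5p.called,
        has_3p_terminus=call_3p.called,
        polya_3p=call_3p.polya,
        completeness="full_length" if full else "partial",
    )


def call_contig(
    contig: Contig,
    alignments: list[ReadAlignment],
    min_support: int = 10,
    polya_min: int = 8,
) -> tuple[TerminusCall, TerminusCall, GenomeSegment]:
    """Convenience wrapper: pileup, call both ends, classify one contig."""
    starts, ends = pileup_read_ends(alignments, contig.contig_id, len(contig.sequence))
    c5 = call_terminus(starts, contig.sequence, "5p", contig.contig_id,
                       min_support=min_support, polya_min=polya_min)
    c3 = call_terminus(ends, contig.sequence, "3p", contig.contig_id,
                       min_support=min_support, polya_min=polya_min)
    return c5, c3, classify_completeness(contig, c5, c3)
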