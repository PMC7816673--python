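"""Cognate-segment grouping by terminal-sequence similarity.

The segments of one multipartite RNA virus share conserved 5' and 3'
terminal sequences.  Within a host strain, full-length segments are grouped
into viruses by single-linkage clustering on the identity of their terminal
words; co-infecting viruses fall apart into disjoint terminal-word families.
Partial segments cannot contribute reliable termini and are passed through
as singleton assemblies flagged incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .termini import GenomeSegment


@dataclass(frozen=True)
class TerminalSimilarity:
    """Ungapped identity of two segments' terminal words.

    ``combined`` is the arithmetic mean of the 5' and 3' scores, taken in
    the better of the two relative orientations (``orientation`` records
    whether segment b was reverse-complemented).
    """

    seg_a: str
    seg_b: str
    score_5p: float
    score_3p: float
    combined: float
    orientation: str = "forward"  # "forward" | "reverse"


@dataclass
class VirusAssembly:
    """A set of cognate segments from one strain: one virus record."""

    virus_id: str
    host_strain: str
    member_segments: list[str]  # ordered by descending length
    n_segments: int = 0
    genome_type: str = "unknown"
    complete: bool = True

    def __post_init__(self):
        if not self.member_segments:
            raise ValueError(f"{self.virus_id}: assembly needs >= 1 member")
        self.n_segments = len(self.member_segments)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _trim_polya(sequence: str) -> str:
    return sequence.rstrip("A")


def extract_termini(segment: GenomeSegment, window: int = 20) -> tuple[str, str]:
    """Return the 5' and 3' terminal words of length ``window``.

    A flagged 3' polyA tail is trimmed before the 3' word is taken, so the
    word reflects virus-specific terminal sequence rather than the tail.
    """
    seq = segment.sequence
    if segment.polya_3p:
        seq = _trim_polya(seq)
    if len(seq) < window:
        raise ValueError(
            f"segment {segment.segment_id!r}: length {len(seq)} after polyA "
            f"trimming is shorter than window {window}"
        )
    return seq[:window], seq[-window:]


def _ungapped_identity(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("terminal words must have equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def terminal_similarity(
    seg_a: GenomeSegment, seg_b: GenomeSegment, window: int = 20
) -> TerminalSimilarity:
    """Score two full-length segments' terminal words in both orientations.

    Deposited strands may differ between cognate segments, so the pair is
    also scored with segment b reverse-complemented (its 5' word then being
    the reverse complement of its 3' word); the better orientation wins.
    """
    for seg in (seg_a, seg_b):
        if not seg.is_full_length:
            raise ValueError(
                f"segment {seg.segment_id!r} is partial; terminal similarity "
                "requires full-length segments"
            )
    a5, a3 = extract_termini(seg_a, window)
    b5, b3 = extract_termini(seg_b, window)

    fwd5 = _ungapped_identity(a5, b5)
    fwd3 = _ungapped_identity(a3, b3)
    rc5 = _ungapped_identity(a5, str(Seq(b3).reverse_complement()))
    rc3 = _ungapped_identity(a3, str(Seq(b5).reverse_complement()))

    forward = (fwd5 + fwd3) / 2
    reverse = (rc5 + rc3) / 2
    if reverse > forward:
        return TerminalSimilarity(seg_a.segment_id, seg_b.segment_id,
                                  rc5, rc3, reverse, orientation="reverse")
    return TerminalSimilarity(seg_a.segment_id, seg_b.segment_id,
                              fwd5, fwd3, forward, orientation="forward")


def group_segments(
    segments: list[GenomeSegment],
    threshold: float = 0.8,
    window: int = 20,
    require_both: bool = False,
) -> list[VirusAssembly]:
    """Partition one strain's segments into virus assemblies.

    Full-length segments are single-linkage clustered: two segments are
    linked when their combined terminal similarity reaches ``threshold``
    (or, with ``require_both``, when both the 5' and 3' scores individually
    do).  Assemblies are deterministic: members ordered by descending
    length then id; assemblies ordered by their longest member.
    """
    if not segments:
        return []
    strains = {s.host_strain for s in segments}
    if len(strains) > 1:
        raise ValueError(f"segments from multiple strains: {sorted(strains)}")
    strain = strains.pop()

    full = sorted(
        (s for s in segments if s.is_full_length),
        key=lambda s: (-len(s.sequence), s.segment_id),
    )
    partial = sorted(
        (s for s in segments if not s.is_full_length),
        key=lambda s: (-len(s.sequence), s.segment_id),
    )

    uf = _UnionFind([s.segment_id for s in full])
    for i, sa in enumerate(full):
        for sb in full[i + 1:]:
            sim = terminal_similarity(sa, sb, window)
            linked = (
                min(sim.score_5p, sim.score_3p) >= threshold
                if require_both
                else sim.combined >= threshold
            )
            if linked:
                uf.union(sa.segment_id, sb.segment_id)

    by_root: dict[str, list[GenomeSegment]] = {}
    for s in full:
        by_root.setdefault(uf.find(s.segment_id), []).append(s)

    clusters = sorted(
        by_root.values(),
        key=lambda ms: (-len(ms[0].sequence), ms[0].segment_id),
    )
    assemblies = []
    for i, members in enumerate(clusters, start=1):
        assemblies.append(
            VirusAssembly(
                virus_id=f"{strain}.v{i:02d}",
                host_strain=strain,
                member_segments=[m.segment_id for m in members],
                complete=True,
            )
        )
    for j, s in enumerate(partial, start=len(assemblies) + 1):
        assemblies.append(
            VirusAssembly(
                virus_id=f"{strain}.v{j:02d}",
                host_strain=strain,
                member_segments=[s.segment_id],
                complete=False,
            )
        )
    return assemblies
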