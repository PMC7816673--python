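"""OTU demarcation and species assignment by nucleotide identity.

RdRp-encoding segments sharing >90% nucleotide identity form one
operational taxonomic unit (OTU, single linkage, strict inequality); an
OTU whose representative shares >95% identity with a known reference is
recognized as that species, otherwise it is a novel species.

Identity is computed from a global pairwise alignment (match +1,
mismatch -1, gap open -2, gap extend -1) as matches divided by alignment
columns (gap columns included); because deposited strands vary, each pair
is scored in the given orientation and with one sequence
reverse-complemented, and the larger identity is reported.  An alternative
denominator, the shorter sequence's length, is available via
``denominator="shorter"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq


@dataclass(frozen=True)
class OtuAssignment:
    otu_id: str
    member_segment_ids: tuple[str, ...]
    representative: str  # longest member
    species_label: str = ""
    novelty: str = "novel"  # "known" | "novel"


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def _identity_one_orientation(a: str, b: str, denominator: str) -> float:
    aln = _aligner().align(a, b)[0]
    counts = aln.counts()
    denom = min(len(a), len(b)) if denominator == "shorter" else aln.length
    return counts.identities / denom * 100.0


def pairwise_nt_identity(
    seq_a: str, seq_b: str, denominator: str = "columns"
) -> float:
    """Percent nucleotide identity of a global alignment, maximized over
    the two relative orientations."""
    if not seq_a or not seq_b:
        raise ValueError("pairwise identity requires non-empty sequences")
    if denominator not in ("columns", "shorter"):
        raise ValueError("denominator must be 'columns' or 'shorter'")
    a = seq_a.upper().replace("U", "T")
    b = seq_b.upper().replace("U", "T")
    fwd = _identity_one_orientation(a, b, denominator)
    rev = _identity_one_orientation(a, str(Seq(b).reverse_complement()), denominator)
    return max(fwd, rev)


def identity_matrix(
    sequences: dict[str, str], denominator: str = "columns"
) -> pd.DataFrame:
    """Symmetric percent-identity matrix (diagonal 100) over segments."""
    ids = list(sequences)
    n = len(ids)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = pairwise_nt_identity(
                sequences[ids[i]], sequences[ids[j]], denominator
            )
            values[i, j] = values[j, i] = pid
    return pd.DataFrame(values, index=ids, columns=ids)


def cluster_otus(
    sequences: dict[str, str],
    matrix: pd.DataFrame,
    otu_threshold: float = 90.0,
) -> list[OtuAssignment]:
    """Single-linkage OTUs: connected components of the graph with an edge
    wherever identity is STRICTLY above ``otu_threshold``.

    The representative is the longest member (ties: lexicographic id);
    OTUs are labeled deterministically in representative order.
    """
    ids = list(matrix.index)
    missing = set(sequences) - set(ids)
    if missing:
        raise ValueError(f"identity matrix lacks segment(s) {sorted(missing)}")

    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    vals = matrix.to_numpy()
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            if vals[i, j] > otu_threshold:
                ra, rb = find(a), find(ids[j])
                if ra != rb:
                    parent[rb] = ra

    groups: dict[str, list[str]] = {}
    for seg in sequences:
        groups.setdefault(find(seg), []).append(seg)

    def rep(members):
        return sorted(members, key=lambda s: (-len(sequences[s]), s))[0]

    clusters = sorted(groups.values(), key=lambda ms: (-len(sequences[rep(ms)]), rep(ms)))
    return [
        OtuAssignment(
            otu_id=f"OTU_{i:02d}",
            member_segment_ids=tuple(sorted(ms, key=lambda s: (-len(sequences[s]), s))),
            representative=rep(ms),
        )
        for i, ms in enumerate(clusters, start=1)
    ]


def assign_species(
    otu: OtuAssignment,
    representative_seq: str,
    references: list[tuple[str, str]],
    species_threshold: float = 95.0,
    novel_name: str | None = None,
    denominator: str = "columns",
) -> OtuAssignment:
    """Label an OTU as a known species (>``species_threshold``% identity of
    its representative to a reference; best hit, ties broken by higher
    identity then lexicographic name) or as a novel species under
    ``novel_name`` (default: 'novel <otu_id>')."""
    best: tuple[float, str] | None = None
    for name, ref_seq in references:
        pid = pairwise_nt_identity(representative_seq, ref_seq, denominator)
        key = (-pid, name)
        if best is None or key < best:
            best = key
    if best is not None and -best[0] > species_threshold:
        return OtuAssignment(
            otu.otu_id, otu.member_segment_ids, otu.representative,
            species_label=best[1], novelty="known",
        )
    label = novel_name if novel_name else f"novel {otu.otu_id}"
    return OtuAssignment(
        otu.otu_id, otu.member_segment_ids, otu.representative,
        species_label=label, novelty="novel",
    )
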