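"""ORF prediction and RdRp catalytic-motif architecture classification.

The RdRp catalytic core carries five conserved motifs in the canonical
order F < A < B < C < D along the protein, motif C containing the
universal GDD triad.  Most RNA viruses encode all five in one ORF
("complete").  Some narnaviruses instead carry F, A and B in the RdRp ORF
of one segment while C/D-like motifs sit in the N-terminal region of an
ORF on a cognate segment — the divided ("split") RdRp architecture.  This
module predicts ORFs, scans them against shipped motif profiles, and
classifies each virus assembly as complete, split, partial or absent.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

from Bio.Seq import Seq

from .grouping import VirusAssembly

#: canonical motif order along the RdRp core
MOTIF_ORDER = ("F", "A", "B", "C", "D")

GENETIC_CODE_TABLES = {"standard": 1, "mold_mito": 4}

_STOPS = {"standard": {"TAA", "TAG", "TGA"}, "mold_mito": {"TAA", "TAG"}}


@dataclass(frozen=True)
class OrfRecord:
    """A predicted ORF; nt coordinates are 0-based half-open on the
    reported strand (i.e. on the reverse complement for strand '-'),
    covering start codon through last sense codon (stop excluded)."""

    orf_id: str
    segment_id: str
    strand: str
    frame: int
    start_nt: int
    end_nt: int
    aa_sequence: str
    genetic_code: str = "standard"

    @property
    def aa_length(self) -> int:
        return len(self.aa_sequence)


@dataclass(frozen=True)
class MotifProfile:
    """Degenerate consensus for one motif; the anchor triplet must match
    exactly, the remaining positions may diverge up to max_mismatches.
    'X' in the pattern matches any residue."""

    label: str
    pattern: str
    anchor: str
    max_mismatches: int

    def __post_init__(self):
        if self.anchor not in self.pattern:
            raise ValueError(
                f"profile {self.label}: anchor {self.anchor!r} not in pattern"
            )

    @property
    def anchor_offset(self) -> int:
        return self.pattern.index(self.anchor)


@dataclass(frozen=True)
class MotifHit:
    orf_id: str
    label: str
    aa_start: int
    aa_end: int
    mismatches: int


@dataclass(frozen=True)
class RdRpArchitecture:
    """Which segments/ORFs carry the RdRp motifs for one virus.

    complete: one ORF carries F,A,B,C,D; split: F/A/B on one segment and a
    qualifying C+D pair in the N-terminal region of an ORF on a different
    segment; partial: F/A/B with no qualifying C/D; absent: otherwise.
    """

    virus_id: str
    classification: str
    fab_carrier: tuple[str, str] | None = None  # (segment_id, orf_id)
    cd_carrier: tuple[str, str] | None = None


def load_motif_profiles(path=None) -> dict[str, MotifProfile]:
    """Load motif profiles from a TSV (default: the packaged profile file)."""
    if path is None:
        source = importlib.resources.files("fldskit.data") / "rdrp_motifs.tsv"
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    profiles: dict[str, MotifProfile] = {}
    header: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        row = dict(zip(header, fields))
        prof = MotifProfile(
            label=row["label"],
            pattern=row["pattern"].upper(),
            anchor=row["anchor"].upper(),
            max_mismatches=int(row["max_mismatches"]),
        )
        profiles[prof.label] = prof
    missing = set(MOTIF_ORDER) - set(profiles)
    if missing:
        raise ValueError(f"profile file lacks motif(s): {sorted(missing)}")
    return profiles


def predict_orfs(
    segment_id: str,
    sequence: str,
    genetic_code: str = "standard",
    min_aa: int = 100,
) -> list[OrfRecord]:
    """All maximal start(ATG)-to-stop ORFs of >= ``min_aa`` codons, on both
    strands and all three frames, under the requested genetic code (the
    mold mitochondrial code reads TGA as tryptophan).  Ordered by
    descending amino-acid length, then id."""
    if genetic_code not in GENETIC_CODE_TABLES:
        raise ValueError(f"unknown genetic code {genetic_code!r}")
    stops = _STOPS[genetic_code]
    table = GENETIC_CODE_TABLES[genetic_code]
    seq = sequence.upper().replace("U", "T")

    orfs: list[OrfRecord] = []
    for strand, strand_seq in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for frame in range(3):
            start_codon = None  # nt offset of the first ATG since last stop
            for pos in range(frame, len(strand_seq) - 2, 3):
                codon = strand_seq[pos:pos + 3]
                if codon in stops:
                    if start_codon is not None and (pos - start_codon) // 3 >= min_aa:
                        cds = strand_seq[start_codon:pos]
                        aa = str(Seq(cds).translate(table=table))
                        orfs.append(
                            OrfRecord(
                                orf_id=f"{segment_id}:{strand}{frame}:{start_codon}",
                                segment_id=segment_id,
                                strand=strand,
                                frame=frame,
                                start_nt=start_codon,
                                end_nt=pos,
                                aa_sequence=aa,
                                genetic_code=genetic_code,
                            )
                        )
                    start_codon = None
                elif codon == "ATG" and start_codon is None:
                    start_codon = pos
    orfs.sort(key=lambda o: (-o.aa_length, o.orf_id))
    return orfs


def _match_at(aa: str, pos: int, profile: MotifProfile) -> int | None:
    """Mismatch count of the profile at ``pos``, or None if unacceptable."""
    window = aa[pos:pos + len(profile.pattern)]
    if len(window) < len(profile.pattern):
        return None
    off = profile.anchor_offset
    if window[off:off + len(profile.anchor)] != profile.anchor:
        return None
    mism = sum(
        1
        for p, a in zip(profile.pattern, window)
        if p != "X" and p != a
    )
    return mism if mism <= profile.max_mismatches else None


def scan_motifs(orf: OrfRecord, profiles: dict[str, MotifProfile]) -> list[MotifHit]:
    """Best non-overlapping hit per motif respecting the canonical order.

    Motifs are assigned left to right (F first): for each label the
    acceptable match with the fewest mismatches (ties: leftmost) starting
    at or after the previous assigned motif's end is taken; labels without
    an acceptable match are absent and do not advance the cursor.
    """
    missing = set(MOTIF_ORDER) - set(profiles)
    if missing:
        raise ValueError(f"profiles must cover F,A,B,C,D; missing {sorted(missing)}")
    aa = orf.aa_sequence
    hits: list[MotifHit] = []
    cursor = 0
    for label in MOTIF_ORDER:
        prof = profiles[label]
        best: tuple[int, int] | None = None  # (mismatches, start)
        for pos in range(cursor, len(aa) - len(prof.pattern) + 1):
            mism = _match_at(aa, pos, prof)
            if mism is not None and (best is None or (mism, pos) < best):
                best = (mism, pos)
        if best is not None:
            mism, pos = best
            hits.append(
                MotifHit(
                    orf_id=orf.orf_id,
                    label=label,
                    aa_start=pos,
                    aa_end=pos + len(prof.pattern),
                    mismatches=mism,
                )
            )
            cursor = pos + len(prof.pattern)
    return hits


def classify_architecture(
    assembly: VirusAssembly,
    orfs: list[OrfRecord],
    hits: list[MotifHit],
    n_term_fraction: float = 0.4,
) -> RdRpArchitecture:
    """Classify a virus's RdRp architecture from motif hits on its ORFs.

    split requires motifs C and D on an ORF of a *different* member
    segment than the F/A/B carrier, with the C hit starting within the
    first ``n_term_fraction`` of that ORF.
    """
    members = set(assembly.member_segments)
    orf_by_id = {o.orf_id: o for o in orfs if o.segment_id in members}
    labels: dict[str, dict[str, MotifHit]] = {}
    for h in hits:
        if h.orf_id in orf_by_id:
            labels.setdefault(h.orf_id, {})[h.label] = h

    def orf_sort_key(orf_id):
        o = orf_by_id[orf_id]
        return (-o.aa_length, o.orf_id)

    # complete: one ORF with all five motifs
    complete = sorted(
        (oid for oid, ls in labels.items() if set(MOTIF_ORDER) <= set(ls)),
        key=orf_sort_key,
    )
    if complete:
        o = orf_by_id[complete[0]]
        carrier = (o.segment_id, o.orf_id)
        return RdRpArchitecture(assembly.virus_id, "complete", carrier, carrier)

    fab = sorted(
        (
            oid
            for oid, ls in labels.items()
            if {"F", "A", "B"} <= set(ls) and not {"C", "D"} & set(ls)
        ),
        key=orf_sort_key,
    )
    # qualifying C/D carriers: C and D present, C within the ORF's N-terminus
    cd = [
        oid
        for oid, ls in labels.items()
        if {"C", "D"} <= set(ls)
        and ls["C"].aa_start < n_term_fraction * orf_by_id[oid].aa_length
    ]
    if fab:
        fab_orf = orf_by_id[fab[0]]
        cd_other = sorted(
            (oid for oid in cd if orf_by_id[oid].segment_id != fab_orf.segment_id),
            key=lambda oid: (labels[oid]["C"].aa_start, oid),
        )
        if cd_other:
            cd_orf = orf_by_id[cd_other[0]]
            return RdRpArchitecture(
                assembly.virus_id,
                "split",
                (fab_orf.segment_id, fab_orf.orf_id),
                (cd_orf.segment_id, cd_orf.orf_id),
            )
        return RdRpArchitecture(
            assembly.virus_id, "partial", (fab_orf.segment_id, fab_orf.orf_id), None
        )
    return RdRpArchitecture(assembly.virus_id, "absent", None, None)


def annotate_assembly(
    assembly: VirusAssembly,
    sequences: dict[str, str],
    genetic_code: str = "standard",
    min_aa: int = 100,
    profiles: dict[str, MotifProfile] | None = None,
    n_term_fraction: float = 0.4,
) -> tuple[list[OrfRecord], list[MotifHit], RdRpArchitecture]:
    """Predict ORFs, scan motifs and classify one assembly in one call."""
    if profiles is None:
        profiles = load_motif_profiles()
    orfs: list[OrfRecord] = []
    for seg_id in assembly.member_segments:
        orfs.extend(predict_orfs(seg_id, sequences[seg_id], genetic_code, min_aa))
    hits: list[MotifHit] = []
    for orf in orfs:
        hits.extend(scan_motifs(orf, profiles))
    arch = classify_architecture(assembly, orfs, hits, n_term_fraction)
    return orfs, hits, arch
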