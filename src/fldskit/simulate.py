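"""Synthetic segmented-virus genomes, terminal-complete reads and truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without external downloads:

* multi-segment genomes whose segments share conserved 5'/3' terminal
  words (the cognate-segment signature), with an optional 3' polyA tail;
* read sets whose alignment boundaries cover the exact genome termini —
  the defining property of adapter-ligated terminal-complete dsRNA
  sequencing — on top of uniform random fragment coverage;
* RdRp ORFs laid out as complete (F,A,B,C,D in one ORF), split (F/A/B on
  one segment, C/D in the N-terminal region of an ORF on a cognate
  segment), partial (F/A/B only) or none;
* co-infection: several viruses resident in one host strain, with
  unrelated terminal words.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .rdrp import GENETIC_CODE_TABLES, MOTIF_ORDER, load_motif_profiles
from .termini import ReadAlignment

NT = np.array(list("ACGT"))

#: default conserved terminal word length (nt)
DEFAULT_TERMINAL_WORD = 20
#: default polyA tail length when a virus carries one (nt)
DEFAULT_POLYA_LEN = 15

# aa offsets of inserted motifs within an ORF translation
_COMPLETE_LAYOUT = {"F": 20, "A": 40, "B": 60, "C": 85, "D": 110}
_FAB_LAYOUT = {"F": 20, "A": 40, "B": 60}
_CD_LAYOUT = {"C": 8, "D": 30}  # within the ORF N-terminus

_MIN_ORF_AA = 130  # hosts the widest layout and clears typical min_aa filters


@dataclass
class VirusSpec:
    """Blueprint for one synthetic virus in one host strain."""

    virus_id: str
    host_strain: str
    n_segments: int
    segment_lengths: list[int]
    terminal_word_5p: str
    terminal_word_3p: str
    polya_len: int = 0
    rdrp_architecture: str = "complete"  # complete | split | partial | none
    genetic_code: str = "standard"
    seed: int = 0

    def __post_init__(self):
        if self.n_segments < 1:
            raise ValueError(f"{self.virus_id}: n_segments must be >= 1")
        if self.n_segments != len(self.segment_lengths):
            raise ValueError(
                f"{self.virus_id}: n_segments != len(segment_lengths)"
            )
        if any(l < 300 for l in self.segment_lengths):
            raise ValueError(f"{self.virus_id}: all segment lengths must be >= 300")
        if self.rdrp_architecture not in ("complete", "split", "partial", "none"):
            raise ValueError(
                f"{self.virus_id}: unknown architecture {self.rdrp_architecture!r}"
            )
        if self.rdrp_architecture == "split" and self.n_segments < 2:
            raise ValueError(f"{self.virus_id}: split architecture needs >= 2 segments")
        if self.genetic_code not in GENETIC_CODE_TABLES:
            raise ValueError(f"{self.virus_id}: unknown genetic code")
        if self.polya_len < 0:
            raise ValueError(f"{self.virus_id}: polya_len must be >= 0")
        for name in ("terminal_word_5p", "terminal_word_3p"):
            word = getattr(self, name).upper().replace("U", "T")
            if not word or set(word) - set("ACGT"):
                raise ValueError(f"{self.virus_id}: invalid {name}")
            setattr(self, name, word)

    @property
    def species(self) -> str:
        """Species token: the virus_id up to the first '.'."""
        return self.virus_id.split(".", 1)[0]


@dataclass(frozen=True)
class SimSegment:
    segment_id: str
    virus_id: str
    host_strain: str
    sequence: str


@dataclass(frozen=True)
class SegmentTruth:
    """Ground truth for one emitted segment (coordinates 0-based)."""

    segment_id: str
    virus_id: str
    species: str
    host_strain: str
    segment_index: int  # 1-based (RNA1, RNA2, ...)
    length: int
    end_5p: int  # always 0
    end_3p: int  # length - 1
    polya: bool
    orf: tuple[int, int] | None  # nt half-open, '+' strand, stop excluded
    motifs: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class SyntheticTruth:
    segments: list[SegmentTruth] = field(default_factory=list)
    strains: dict[str, list[str]] = field(default_factory=dict)  # strain -> virus_ids

    def by_segment(self) -> dict[str, SegmentTruth]:
        return {t.segment_id: t for t in self.segments}

    def architecture_of(self) -> dict[str, str]:
        """virus_id -> true RdRp architecture (from recorded motif layouts)."""
        out: dict[str, str] = {}
        by_virus: dict[str, list[SegmentTruth]] = {}
        for t in self.segments:
            by_virus.setdefault(t.virus_id, []).append(t)
        for vid, segs in by_virus.items():
            labels = {m for t in segs for m in t.motifs}
            carriers = {t.segment_id for t in segs if t.motifs}
            if labels >= set(MOTIF_ORDER) and len(carriers) == 1:
                out[vid] = "complete"
            elif labels >= set(MOTIF_ORDER):
                out[vid] = "split"
            elif {"F", "A", "B"} <= labels:
                out[vid] = "partial"
            else:
                out[vid] = "absent"
        return out


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(NT[rng.integers(0, 4, size=n)])


def random_terminal_words(
    rng: np.random.Generator, length: int = DEFAULT_TERMINAL_WORD
) -> tuple[str, str]:
    """Random conserved terminal words; the 3' word never ends in A so a
    downstream polyA tail remains distinguishable from virus sequence."""
    w5 = _random_dna(rng, length)
    w3 = _random_dna(rng, length)
    if w3.endswith("A"):
        w3 = w3[:-1] + "CGT"[rng.integers(0, 3)]
    return w5, w3


def _sense_codons(genetic_code: str) -> dict[str, list[str]]:
    """aa -> sorted list of codons under the genetic code."""
    table = CodonTable.unambiguous_dna_by_id[GENETIC_CODE_TABLES[genetic_code]]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        by_aa.setdefault(aa, []).append(codon)
    return by_aa


def _encode_orf(
    rng: np.random.Generator,
    aa_len: int,
    motif_layout: dict[str, int],
    genetic_code: str,
    profiles,
) -> tuple[str, str, dict[str, tuple[int, int]]]:
    """Build an ORF: random amino acids with motif consensus strings
    overwritten at fixed offsets, back-translated through random
    synonymous codons.  Returns (cds_nt_without_stop, aa, motif_intervals)."""
    by_aa = _sense_codons(genetic_code)
    alphabet = sorted(by_aa)
    aa = ["M"] + [alphabet[rng.integers(0, len(alphabet))] for _ in range(aa_len - 1)]
    intervals: dict[str, tuple[int, int]] = {}
    for label, start in motif_layout.items():
        pattern = profiles[label].pattern
        if start + len(pattern) > aa_len:
            raise ValueError("motif layout exceeds ORF length")
        aa[start:start + len(pattern)] = list(pattern)
        intervals[label] = (start, start + len(pattern))
    codons = []
    for i, res in enumerate(aa):
        if i == 0:
            codons.append("ATG")
        else:
            options = by_aa[res]
            codons.append(options[rng.integers(0, len(options))])
    return "".join(codons), "".join(aa), intervals


def generate_genome(spec: VirusSpec) -> tuple[list[SimSegment], list[SegmentTruth]]:
    """Generate all segments of one virus plus per-segment ground truth.

    Every segment starts with the virus's shared 5' terminal word and ends
    with the shared 3' word (followed by the polyA tail if requested).
    Segment 1 carries the RdRp ORF demanded by the architecture; under
    ``split`` the C/D motifs go into the N-terminus of an ORF on segment 2.
    Interior sequence is uniform random from the seed; an in-frame stop is
    planted directly upstream of each ORF start so the ORF is maximal.
    """
    rng = np.random.default_rng(spec.seed)
    profiles = load_motif_profiles()
    w5, w3 = spec.terminal_word_5p, spec.terminal_word_3p
    W5, W3 = len(w5), len(w3)

    layouts: dict[int, dict[str, int] | None] = {}  # segment index (0-based) -> layout
    arch = spec.rdrp_architecture
    if arch == "complete":
        layouts[0] = _COMPLETE_LAYOUT
    elif arch == "split":
        layouts[0] = _FAB_LAYOUT
        layouts[1] = _CD_LAYOUT
    elif arch == "partial":
        layouts[0] = _FAB_LAYOUT
    else:
        layouts[0] = {}  # a plain ORF without motifs

    segments: list[SimSegment] = []
    truths: list[SegmentTruth] = []
    for i, length in enumerate(spec.segment_lengths):
        layout = layouts.get(i)
        seg_id = f"{spec.virus_id}.RNA{i + 1}"
        interior = length - W5 - W3
        orf = None
        motifs: dict[str, tuple[int, int]] = {}
        if layout is not None:
            # w5 | pad | TAA | ATG..cds.. | stop | pad | w3
            need_nt = 3 * _MIN_ORF_AA + 6  # cds + flanking stop codons
            if interior < need_nt + 20:
                raise ValueError(
                    f"{spec.virus_id} segment {i + 1}: length {length} nt is too "
                    f"short to host the requested ORF "
                    f"(needs >= {need_nt + 20 + W5 + W3} nt)"
                )
            orf_aa = min((interior - 26) // 3, 220)
            cds, _aa, motifs = _encode_orf(
                rng, orf_aa, layout, spec.genetic_code, profiles
            )
            lead = rng.integers(10, interior - len(cds) - 6 - 10 + 1)
            pad_r = interior - lead - 3 - len(cds) - 3
            seq = (
                w5
                + _random_dna(rng, lead)
                + "TAA"
                + cds
                + "TAA"
                + _random_dna(rng, pad_r)
                + w3
            )
            orf_start = W5 + lead + 3
            orf = (orf_start, orf_start + len(cds))
        else:
            seq = w5 + _random_dna(rng, interior) + w3
        assert len(seq) == length
        seq = seq + "A" * spec.polya_len
        segments.append(
            SimSegment(seg_id, spec.virus_id, spec.host_strain, seq)
        )
        truths.append(
            SegmentTruth(
                segment_id=seg_id,
                virus_id=spec.virus_id,
                species=spec.species,
                host_strain=spec.host_strain,
                segment_index=i + 1,
                length=len(seq),
                end_5p=0,
                end_3p=len(seq) - 1,
                polya=spec.polya_len > 0,
                orf=orf,
                motifs=motifs,
            )
        )
    return segments, truths


def simulate_flds_reads(
    segments: list[SimSegment],
    depth: float = 30.0,
    read_len: int = 150,
    seed: int = 0,
    terminal_reads_per_end: int = 15,
    error_rate: float = 0.0,
) -> tuple[list[tuple[str, str, str]], list[ReadAlignment]]:
    """Simulate error-free (or uniformly perturbed) reads with exact
    terminal coverage.

    Per segment, ``round(depth * L / read_len)`` reads are tiled from
    uniform random start positions, plus ``terminal_reads_per_end`` reads
    whose alignment boundary coincides exactly with each true terminus.
    Returns (FASTQ tuples, coordinate-sorted alignments).
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str, str]] = []
    alignments: list[ReadAlignment] = []

    def emit(seg: SimSegment, read_id: str, start: int, length: int):
        end = start + length
        frag = seg.sequence[start:end]
        if error_rate > 0:
            bases = np.array(list(frag))
            hit = rng.random(len(bases)) < error_rate
            if hit.any():
                subs = NT[rng.integers(0, 4, size=int(hit.sum()))]
                bases[hit] = subs
                frag = "".join(bases)
        strand = "+" if rng.random() < 0.5 else "-"
        out_seq = frag if strand == "+" else str(Seq(frag).reverse_complement())
        reads.append((read_id, out_seq, "I" * len(out_seq)))
        alignments.append(
            ReadAlignment(read_id, seg.segment_id, start, end, strand)
        )

    for seg in segments:
        L = len(seg.sequence)
        if read_len >= L:
            raise ValueError(
                f"read_len {read_len} must be shorter than segment "
                f"{seg.segment_id!r} ({L} nt)"
            )
        n_random = int(round(depth * L / read_len))
        if n_random + 2 * terminal_reads_per_end == 0:
            raise ValueError(
                f"segment {seg.segment_id!r}: depth {depth} yields zero reads"
            )
        for k in range(n_random):
            start = int(rng.integers(0, L - read_len + 1))
            emit(seg, f"{seg.segment_id}/r{k:05d}", start, read_len)
        # adapter-ligated terminal fragments: the alignment boundary falls
        # exactly on the genome end; the inner boundary varies with the
        # fragment length, as in real libraries
        for k in range(terminal_reads_per_end):
            len5 = int(rng.integers(max(read_len // 2, 1), read_len + 1))
            emit(seg, f"{seg.segment_id}/t5_{k:02d}", 0, len5)
            len3 = int(rng.integers(max(read_len // 2, 1), read_len + 1))
            emit(seg, f"{seg.segment_id}/t3_{k:02d}", L - len3, len3)

    alignments.sort(key=lambda a: (a.contig_id, a.start, a.read_id))
    return reads, alignments


@dataclass
class StrainPlan:
    strain: str
    specs: list[VirusSpec]


def _species_seed(master: int, index: int) -> int:
    h = hashlib.sha256(f"{master}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def default_study(seed: int = 0) -> list[StrainPlan]:
    """The default synthetic screen: 10 host strains, 12 virus residencies.

    Covers the structures the analysis must resolve: 1- to 4-segment
    genomes; two co-infected strains (one with two viruses, one with
    three); one split-RdRp virus; one partial and one motif-less RdRp;
    one species resident in two strains (so two records share an OTU);
    polyA tails on three monopartite viruses.  Terminal words are drawn
    independently per species (20 nt), genome interiors independently per
    virus; everything derives deterministically from ``seed``.
    """
    catalog = [
        # species, n_segments, lengths, architecture, polyA
        ("V01", [2400, 1800, 1300, 900], "complete", 0),
        ("V02", [1600], "complete", DEFAULT_POLYA_LEN),
        ("V03", [2000, 1500, 1000], "split", 0),
        ("V04", [1400], "complete", DEFAULT_POLYA_LEN),
        ("V05", [1700, 1100], "partial", 0),
        ("V06", [2100, 1600, 1200], "complete", 0),
        ("V07", [1900, 1000], "complete", 0),
        ("V08", [1500], "complete", DEFAULT_POLYA_LEN),
        ("V09", [1300], "none", 0),
        ("V10", [1200], "complete", 0),
        ("V11", [2200, 1400, 950], "complete", 0),
        ("V12", [2300, 1700, 1250, 900], "complete", 0),
    ]
    residency = {
        "S01": ["V01", "V02"],
        "S02": ["V03", "V04", "V05"],
        "S03": ["V06"],
        "S04": ["V06"],  # same species in a second strain: shared OTU
        "S05": ["V07"],
        "S06": ["V08"],
        "S07": ["V09"],
        "S08": ["V10"],
        "S09": ["V11"],
        "S10": ["V12"],
    }
    by_species = {}
    for idx, (name, lengths, arch, polya) in enumerate(catalog):
        sp_seed = _species_seed(seed, idx)
        w5, w3 = random_terminal_words(np.random.default_rng(sp_seed))
        by_species[name] = (lengths, arch, polya, sp_seed, w5, w3)

    plans = []
    for strain in sorted(residency):
        specs = []
        for name in residency[strain]:
            lengths, arch, polya, sp_seed, w5, w3 = by_species[name]
            specs.append(
                VirusSpec(
                    virus_id=f"{name}.{strain}",
                    host_strain=strain,
                    n_segments=len(lengths),
                    segment_lengths=list(lengths),
                    terminal_word_5p=w5,
                    terminal_word_3p=w3,
                    polya_len=polya,
                    rdrp_architecture=arch,
                    seed=sp_seed,  # same species => identical genome
                )
            )
        plans.append(StrainPlan(strain=strain, specs=specs))
    return plans


@dataclass
class StudyData:
    """All simulated material for one study, keyed by strain."""

    segments: dict[str, list[SimSegment]]
    reads: dict[str, list[tuple[str, str, str]]]
    alignments: dict[str, list[ReadAlignment]]
    truth: SyntheticTruth


def simulate_study(
    plans: list[StrainPlan],
    depth: float = 30.0,
    read_len: int = 150,
    terminal_reads_per_end: int = 15,
    error_rate: float = 0.0,
    seed: int = 0,
) -> StudyData:
    """Generate genomes and reads for every strain in a study plan."""
    truth = SyntheticTruth()
    segments: dict[str, list[SimSegment]] = {}
    reads: dict[str, list] = {}
    alignments: dict[str, list] = {}
    for si, plan in enumerate(plans):
        strain_segments: list[SimSegment] = []
        truth.strains[plan.strain] = [s.virus_id for s in plan.specs]
        for spec in plan.specs:
            segs, truths = generate_genome(spec)
            strain_segments.extend(segs)
            truth.segments.extend(truths)
        r, a = simulate_flds_reads(
            strain_segments,
            depth=depth,
            read_len=read_len,
            seed=_species_seed(seed, 1000 + si),
            terminal_reads_per_end=terminal_reads_per_end,
            error_rate=error_rate,
        )
        segments[plan.strain] = strain_segments
        reads[plan.strain] = r
        alignments[plan.strain] = a
    return StudyData(segments=segments, reads=reads, alignments=alignments, truth=truth)


def make_screen_fixture(path=None):
    """The packaged 20-record strain-virus screening table; optionally
    written to ``path`` as TSV."""
    from .report import load_table1

    df = load_table1()
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
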