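"""File I/O and pipeline configuration.

FASTA/FASTQ go through Biopython, SAM through pysam, tables through pandas.
SAM coordinates (1-based POS) are converted to the internal 0-based
half-open convention on read.  Any ``U`` in input nucleotide sequences is
normalized to ``T`` (cDNA convention).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .termini import ReadAlignment

_VALID_NT = set("ACGTN")


class FormatError(ValueError):
    """Malformed input file."""


def normalize_nt(sequence: str, where: str = "sequence") -> str:
    """Uppercase, RNA->DNA (U->T), and validate the alphabet."""
    seq = str(sequence).upper().replace("U", "T")
    bad = set(seq) - _VALID_NT
    if bad:
        raise FormatError(f"{where}: invalid nucleotide(s) {sorted(bad)}")
    return seq


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        records[rec.id] = normalize_nt(str(rec.seq), where=f"{path}:{rec.id}")
    return records


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]], path) -> None:
    if isinstance(records, Mapping):
        records = records.items()
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read FASTQ as ``(read_id, sequence, quality_string)`` tuples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(reads: Iterable[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def write_sam(
    alignments: Iterable[ReadAlignment],
    contig_lengths: Mapping[str, int],
    path,
) -> None:
    """Write ungapped alignments as plain-text SAM (1-based POS)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, length in contig_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        rows = sorted(alignments, key=lambda a: (a.contig_id, a.start, a.read_id))
        for a in rows:
            flag = 16 if a.strand == "-" else 0
            cigar = f"{a.end - a.start}M"
            fh.write(
                f"{a.read_id}\t{flag}\t{a.contig_id}\t{a.start + 1}\t60\t{cigar}"
                f"\t*\t0\t0\t*\t*\n"
            )


def read_sam(path) -> list[ReadAlignment]:
    """Read alignments from SAM; POS converted to 0-based start."""
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            out.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    contig_id=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                )
            )
    return out


def read_tsv(path, required: Iterable[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


_GENETIC_CODES = ("standard", "mold_mito")


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters with their documented defaults.

    The terminus rule uses a strict inequality: support must exceed
    ``min_support`` (default 10, i.e. "more than ten reads").
    """

    seed: int = 0
    outdir: str = "fldskit_run"
    # read simulation
    depth: float = 30.0
    read_len: int = 150
    terminal_reads_per_end: int = 15
    error_rate: float = 0.0
    # terminus calling
    min_support: int = 10
    polya_min: int = 8
    # segment grouping
    window: int = 20
    group_threshold: float = 0.8
    require_both: bool = False
    # RdRp annotation
    genetic_code: str = "standard"
    min_orf_aa: int = 100
    n_term_fraction: float = 0.4
    # OTU / species demarcation (percent identity, strict >)
    otu_threshold: float = 90.0
    species_threshold: float = 95.0

    def __post_init__(self):
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if self.terminal_reads_per_end < 0:
            raise ValueError("terminal_reads_per_end must be >= 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.min_support < 0:
            raise ValueError("min_support must be >= 0")
        if self.polya_min < 1:
            raise ValueError("polya_min must be >= 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0 < self.group_threshold <= 1:
            raise ValueError("group_threshold must be in (0, 1]")
        if self.genetic_code not in _GENETIC_CODES:
            raise ValueError(f"genetic_code must be one of {_GENETIC_CODES}")
        if self.min_orf_aa < 1:
            raise ValueError("min_orf_aa must be >= 1")
        if not 0 < self.n_term_fraction <= 1:
            raise ValueError("n_term_fraction must be in (0, 1]")
        for name in ("otu_threshold", "species_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percent in [0, 100]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
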