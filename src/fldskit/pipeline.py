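"""End-to-end orchestration: simulate -> call termini -> group -> annotate
-> classify -> report, plus truth-based evaluation of a run.

The pipeline operates in memory and optionally writes every stage output
to an append-only run directory together with a machine-readable manifest
(parameters, seed, package version, input hashes, timestamp).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .grouping import VirusAssembly, group_segments
from .io import PipelineConfig, write_fasta, write_fastq, write_sam, write_tsv
from .otu import OtuAssignment, assign_species, cluster_otus, identity_matrix
from .rdrp import (
    MotifHit,
    OrfRecord,
    RdRpArchitecture,
    annotate_assembly,
    load_motif_profiles,
)
from .report import ScreenSummary, render_table, tally_screen
from .simulate import StudyData, default_study, simulate_study
from .termini import GenomeSegment, TerminusCall, call_contig, Contig


@dataclass
class PipelineResult:
    config: PipelineConfig
    calls: list[TerminusCall]
    segments: dict[str, list[GenomeSegment]]  # strain -> segments
    assemblies: list[VirusAssembly]
    orfs: list[OrfRecord]
    hits: list[MotifHit]
    architectures: list[RdRpArchitecture]
    otus: list[OtuAssignment]
    otu_of_assembly: dict[str, str]  # virus_id -> otu_id
    records: pd.DataFrame
    summary: ScreenSummary
    manifest: dict


def _hash_sequences(study: StudyData) -> str:
    h = hashlib.sha256()
    for strain in sorted(study.segments):
        for seg in study.segments[strain]:
            h.update(seg.segment_id.encode())
            h.update(seg.sequence.encode())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    study: StudyData | None = None,
    outdir: str | Path | None = None,
) -> tuple[StudyData, PipelineResult]:
    """Run every stage on a simulated study (default: the built-in
    10-strain study plan under ``config.seed``)."""
    if study is None:
        study = simulate_study(
            default_study(config.seed),
            depth=config.depth,
            read_len=config.read_len,
            terminal_reads_per_end=config.terminal_reads_per_end,
            error_rate=config.error_rate,
            seed=config.seed,
        )

    profiles = load_motif_profiles()
    calls: list[TerminusCall] = []
    segments: dict[str, list[GenomeSegment]] = {}
    assemblies: list[VirusAssembly] = []
    orfs: list[OrfRecord] = []
    hits: list[MotifHit] = []
    architectures: list[RdRpArchitecture] = []
    sequences: dict[str, str] = {}

    for strain in sorted(study.segments):
        strain_segments = []
        by_contig: dict[str, list] = {}
        for aln in study.alignments[strain]:
            by_contig.setdefault(aln.contig_id, []).append(aln)
        for sim_seg in study.segments[strain]:
            sequences[sim_seg.segment_id] = sim_seg.sequence
            contig = Contig(sim_seg.segment_id, sim_seg.sequence, strain)
            c5, c3, seg = call_contig(
                contig,
                by_contig.get(sim_seg.segment_id, []),
                min_support=config.min_support,
                polya_min=config.polya_min,
            )
            calls.extend([c5, c3])
            strain_segments.append(seg)
        segments[strain] = strain_segments
        strain_assemblies = group_segments(
            strain_segments,
            threshold=config.group_threshold,
            window=config.window,
            require_both=config.require_both,
        )
        assemblies.extend(strain_assemblies)
        for asm in strain_assemblies:
            a_orfs, a_hits, arch = annotate_assembly(
                asm,
                sequences,
                genetic_code=config.genetic_code,
                min_aa=config.min_orf_aa,
                profiles=profiles,
                n_term_fraction=config.n_term_fraction,
            )
            orfs.extend(a_orfs)
            hits.extend(a_hits)
            architectures.append(arch)

    # OTU clustering over RdRp-carrier segments; assemblies without an
    # RdRp carrier become their own singleton OTUs.
    arch_by_virus = {a.virus_id: a for a in architectures}
    carrier_of: dict[str, str] = {}  # virus_id -> carrier segment_id
    for asm in assemblies:
        arch = arch_by_virus[asm.virus_id]
        if arch.fab_carrier is not None:
            carrier_of[asm.virus_id] = arch.fab_carrier[0]
    carrier_seqs = {seg: sequences[seg] for seg in carrier_of.values()}
    otus: list[OtuAssignment] = []
    otu_of_assembly: dict[str, str] = {}
    if carrier_seqs:
        matrix = identity_matrix(carrier_seqs)
        clusters = cluster_otus(carrier_seqs, matrix, config.otu_threshold)
        for otu in clusters:
            labeled = assign_species(
                otu,
                carrier_seqs[otu.representative],
                references=[],
                species_threshold=config.species_threshold,
            )
            otus.append(labeled)
        seg_to_otu = {
            seg: otu.otu_id for otu in otus for seg in otu.member_segment_ids
        }
        for vid, carrier in carrier_of.items():
            otu_of_assembly[vid] = seg_to_otu[carrier]
    next_idx = len(otus) + 1
    for asm in assemblies:
        if asm.virus_id not in otu_of_assembly:
            otu_id = f"OTU_{next_idx:02d}"
            next_idx += 1
            otus.append(
                OtuAssignment(
                    otu_id=otu_id,
                    member_segment_ids=tuple(asm.member_segments[:1]),
                    representative=asm.member_segments[0],
                    species_label=f"novel {otu_id}",
                    novelty="novel",
                )
            )
            otu_of_assembly[asm.virus_id] = otu_id

    otu_by_id = {o.otu_id: o for o in otus}
    records = pd.DataFrame(
        [
            {
                "strain": asm.host_strain,
                "species": "Synthetic sp.",
                "virus_name": otu_by_id[otu_of_assembly[asm.virus_id]].species_label,
                "virus_abbrev": asm.virus_id,
                "n_segments": asm.n_segments,
                "genome_type": asm.genome_type,
                "method": "FLDS",
                "novel": otu_by_id[otu_of_assembly[asm.virus_id]].novelty == "novel",
                "complete_sequence": asm.complete,
                "termini_complete": asm.complete,
            }
            for asm in assemblies
        ]
    )
    summary = tally_screen(records, {"Synthetic sp.": len(study.segments)})

    manifest = {
        "package": "fldskit",
        "version": __version__,
        "parameters": config.to_dict(),
        "seed": config.seed,
        "n_strains": len(study.segments),
        "genome_sha256": _hash_sequences(study),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    result = PipelineResult(
        config=config,
        calls=calls,
        segments=segments,
        assemblies=assemblies,
        orfs=orfs,
        hits=hits,
        architectures=architectures,
        otus=otus,
        otu_of_assembly=otu_of_assembly,
        records=records,
        summary=summary,
        manifest=manifest,
    )
    if outdir is not None:
        write_run(Path(outdir), study, result)
    return study, result


def write_run(outdir: Path, study: StudyData, result: PipelineResult) -> None:
    """Write every stage output plus the run manifest to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for strain, segs in study.segments.items():
        sdir = outdir / strain
        sdir.mkdir(exist_ok=True)
        write_fasta({s.segment_id: s.sequence for s in segs}, sdir / "genomes.fasta")
        write_fastq(study.reads[strain], sdir / "reads.fastq")
        write_sam(
            study.alignments[strain],
            {s.segment_id: len(s.sequence) for s in segs},
            sdir / "alignments.sam",
        )
    write_tsv(
        pd.DataFrame([dataclasses.asdict(c) for c in result.calls]),
        outdir / "termini.tsv",
    )
    write_tsv(
        pd.DataFrame(
            [
                {k: v for k, v in dataclasses.asdict(s).items() if k != "sequence"}
                for segs in result.segments.values()
                for s in segs
            ]
        ),
        outdir / "segments.tsv",
    )
    write_tsv(
        pd.DataFrame(
            [
                {
                    "virus_id": a.virus_id,
                    "host_strain": a.host_strain,
                    "members": ",".join(a.member_segments),
                    "n_segments": a.n_segments,
                    "complete": a.complete,
                    "otu_id": result.otu_of_assembly[a.virus_id],
                }
                for a in result.assemblies
            ]
        ),
        outdir / "assemblies.tsv",
    )
    write_tsv(
        pd.DataFrame([dataclasses.asdict(o) for o in result.orfs]),
        outdir / "orfs.tsv",
    )
    write_tsv(
        pd.DataFrame([dataclasses.asdict(h) for h in result.hits]),
        outdir / "motif_hits.tsv",
    )
    write_tsv(
        pd.DataFrame([dataclasses.asdict(a) for a in result.architectures]),
        outdir / "architecture.tsv",
    )
    write_tsv(
        pd.DataFrame(
            [
                {
                    "otu_id": o.otu_id,
                    "members": ",".join(o.member_segment_ids),
                    "representative": o.representative,
                    "species": o.species_label,
                    "novelty": o.novelty,
                }
                for o in result.otus
            ]
        ),
        outdir / "otus.tsv",
    )
    table, text = render_table(result.summary, result.records)
    write_tsv(table, outdir / "records.tsv")
    (outdir / "report.txt").write_text(text + "\n")
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2) + "\n")


def evaluate_against_truth(study: StudyData, result: PipelineResult) -> dict:
    """Truth-based quality metrics of a pipeline run on synthetic data.

    Returns terminus recall, completeness accuracy, segment-grouping ARI,
    the RdRp-architecture confusion diagonal, and the OTU-vs-species ARI
    (1.0 everywhere means exact recovery).
    """
    truth_by_seg = study.truth.by_segment()

    call_index = {(c.contig_id, c.side): c for c in result.calls}
    n_termini = 0
    n_called = 0
    for seg_id in truth_by_seg:
        for side in ("5p", "3p"):
            n_termini += 1
            c = call_index.get((seg_id, side))
            if c is not None and c.called:
                n_called += 1
    terminus_recall = n_called / n_termini if n_termini else 0.0

    n_seg = 0
    n_correct = 0
    for segs in result.segments.values():
        for s in segs:
            n_seg += 1
            if s.completeness == "full_length":  # all truth segments are complete
                n_correct += 1
    completeness_accuracy = n_correct / n_seg if n_seg else 0.0

    seg_ids = sorted(truth_by_seg)
    truth_labels = [truth_by_seg[s].virus_id for s in seg_ids]
    asm_of_seg = {
        m: a.virus_id for a in result.assemblies for m in a.member_segments
    }
    pred_labels = [asm_of_seg.get(s, "unassigned") for s in seg_ids]
    grouping_ari = float(adjusted_rand_score(truth_labels, pred_labels))

    # architecture: map each assembly to its truth virus by member majority
    truth_arch = study.truth.architecture_of()
    arch_by_virus = {a.virus_id: a.classification for a in result.architectures}
    n_arch = 0
    n_arch_ok = 0
    confusion: dict[tuple[str, str], int] = {}
    for asm in result.assemblies:
        viruses = [truth_by_seg[m].virus_id for m in asm.member_segments]
        true_virus = max(set(viruses), key=viruses.count)
        t = truth_arch[true_virus]
        p = arch_by_virus[asm.virus_id]
        confusion[(t, p)] = confusion.get((t, p), 0) + 1
        n_arch += 1
        n_arch_ok += t == p
    architecture_accuracy = n_arch_ok / n_arch if n_arch else 0.0

    truth_species = []
    pred_otu = []
    for asm in result.assemblies:
        viruses = [truth_by_seg[m].virus_id for m in asm.member_segments]
        true_virus = max(set(viruses), key=viruses.count)
        truth_species.append(truth_by_seg[asm.member_segments[0]].species
                             if true_virus is None else true_virus.split(".", 1)[0])
        pred_otu.append(result.otu_of_assembly[asm.virus_id])
    otu_ari = float(adjusted_rand_score(truth_species, pred_otu))

    return {
        "terminus_recall": terminus_recall,
        "completeness_accuracy": completeness_accuracy,
        "grouping_ari": grouping_ari,
        "architecture_accuracy": architecture_accuracy,
        "architecture_confusion": confusion,
        "otu_ari": otu_ari,
        "n_segments": n_seg,
        "n_assemblies": len(result.assemblies),
    }
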