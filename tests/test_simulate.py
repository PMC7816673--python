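"""Synthetic-virome generator: determinism, truth consistency, terminal
words, read/terminal coverage and the packaged screening fixture."""

import numpy as np
import pytest
from Bio.Seq import Seq

from fldskit.simulate import (
    DEFAULT_TERMINAL_WORD,
    default_study,
    generate_genome,
    make_screen_fixture,
    simulate_flds_reads,
    simulate_study,
)

from conftest import make_spec


class TestGenerateGenome:
    def test_deterministic_under_fixed_seed(self):
        spec = make_spec(lengths=(1500, 900), seed=3)
        segs_a, truth_a = generate_genome(spec)
        segs_b, truth_b = generate_genome(make_spec(lengths=(1500, 900), seed=3))
        assert [s.sequence for s in segs_a] == [s.sequence for s in segs_b]
        assert truth_a == truth_b

    def test_segments_share_terminal_words(self):
        spec = make_spec(lengths=(2000, 1400, 900), seed=5)
        segs, _ = generate_genome(spec)
        assert len(segs) == 3
        for s in segs:
            assert s.sequence.startswith(spec.terminal_word_5p)
            assert s.sequence.endswith(spec.terminal_word_3p)

    def test_polya_appended_after_terminal_word(self):
        spec = make_spec(lengths=(1500,), polya_len=15, seed=8)
        (seg,), (truth,) = generate_genome(spec)
        assert seg.sequence.endswith(spec.terminal_word_3p + "A" * 15)
        assert truth.polya
        assert truth.length == 1515
        assert truth.end_3p == 1514

    def test_complete_architecture_all_five_motifs_in_order(self, profiles):
        spec = make_spec(lengths=(1800,), architecture="complete", seed=2)
        (seg,), (truth,) = generate_genome(spec)
        assert set(truth.motifs) == {"F", "A", "B", "C", "D"}
        starts = [truth.motifs[m][0] for m in ("F", "A", "B", "C", "D")]
        assert starts == sorted(starts)

    def test_split_architecture_cd_on_second_segment_n_terminus(self):
        spec = make_spec(lengths=(2000, 1500), architecture="split", seed=1)
        segs, truth = generate_genome(spec)
        t1, t2 = truth
        assert set(t1.motifs) == {"F", "A", "B"}
        assert set(t2.motifs) == {"C", "D"}
        assert t2.segment_index == 2
        orf_start, orf_end = t2.orf
        orf_aa_len = (orf_end - orf_start) // 3
        assert t2.motifs["C"][0] < 0.4 * orf_aa_len

    def test_truth_motif_intervals_translate_to_anchor(self, profiles):
        for arch in ("complete", "split", "partial"):
            spec = make_spec(lengths=(2000, 1500), architecture=arch, seed=13)
            segs, truth = generate_genome(spec)
            seq_of = {s.segment_id: s.sequence for s in segs}
            for t in truth:
                if not t.motifs:
                    continue
                start, end = t.orf
                aa = str(Seq(seq_of[t.segment_id][start:end]).translate())
                for label, (a, b) in t.motifs.items():
                    assert profiles[label].anchor in aa[a:b]

    def test_segment_too_short_for_orf_rejected(self):
        with pytest.raises(ValueError, match="too short to host"):
            generate_genome(make_spec(lengths=(320,), architecture="complete"))

    def test_invalid_specs_rejected(self):
        from fldskit.simulate import VirusSpec

        with pytest.raises(ValueError, match="n_segments"):
            VirusSpec("v", "s", 2, [1500], "ACGT", "ACGT")
        with pytest.raises(ValueError, match="split"):
            make_spec(lengths=(1500,), architecture="split")


class TestSimulateReads:
    def test_terminal_reads_cover_exact_termini(self):
        spec = make_spec(lengths=(1000,), seed=4, architecture="none")
        segs, _ = generate_genome(spec)
        _, alns = simulate_flds_reads(segs, depth=10, read_len=120, seed=0,
                                      terminal_reads_per_end=15)
        L = len(segs[0].sequence)
        assert sum(a.start == 0 for a in alns) >= 15
        assert sum(a.end == L for a in alns) >= 15

    def test_depth_controls_emitted_bases(self):
        spec = make_spec(lengths=(1000,), seed=4, architecture="none")
        segs, _ = generate_genome(spec)
        reads, _ = simulate_flds_reads(segs, depth=50, read_len=100, seed=0,
                                       terminal_reads_per_end=15)
        random_bases = sum(
            len(seq) for rid, seq, _ in reads if "/r" in rid
        )
        assert abs(random_bases / 1000 - 50) <= 0.2 * 50

    def test_deterministic_reads(self):
        spec = make_spec(lengths=(900,), seed=4, architecture="none")
        segs, _ = generate_genome(spec)
        r1, a1 = simulate_flds_reads(segs, depth=5, read_len=100, seed=9)
        r2, a2 = simulate_flds_reads(segs, depth=5, read_len=100, seed=9)
        assert r1 == r2 and a1 == a2

    def test_read_longer_than_segment_rejected(self):
        spec = make_spec(lengths=(900,), seed=4, architecture="none")
        segs, _ = generate_genome(spec)
        with pytest.raises(ValueError, match="read_len"):
            simulate_flds_reads(segs, depth=5, read_len=900, seed=0)

    def test_zero_depth_rejected(self):
        spec = make_spec(lengths=(900,), seed=4, architecture="none")
        segs, _ = generate_genome(spec)
        with pytest.raises(ValueError, match="depth"):
            simulate_flds_reads(segs, depth=0, read_len=100, seed=0)


class TestStudyPlan:
    def test_default_study_structure(self):
        plans = default_study(0)
        assert len(plans) == 10
        n_viruses = {p.strain: len(p.specs) for p in plans}
        assert sorted(n_viruses.values(), reverse=True)[:2] == [3, 2]  # co-infections
        archs = [s.rdrp_architecture for p in plans for s in p.specs]
        assert archs.count("split") == 1
        assert {s.n_segments for p in plans for s in p.specs} == {1, 2, 3, 4}

    def test_shared_species_identical_genomes_across_strains(self):
        plans = {p.strain: p for p in default_study(0)}
        spec_a = plans["S03"].specs[0]
        spec_b = plans["S04"].specs[0]
        assert spec_a.species == spec_b.species
        segs_a, _ = generate_genome(spec_a)
        segs_b, _ = generate_genome(spec_b)
        assert [s.sequence for s in segs_a] == [s.sequence for s in segs_b]

    def test_study_truth_covers_every_segment(self):
        study = simulate_study(default_study(2)[:3], depth=5, read_len=100, seed=2)
        emitted = {s.segment_id for segs in study.segments.values() for s in segs}
        assert {t.segment_id for t in study.truth.segments} == emitted
        contigs = {a.contig_id for alns in study.alignments.values() for a in alns}
        assert contigs == emitted


class TestScreenFixture:
    def test_twenty_records_seventeen_strains(self):
        df = make_screen_fixture()
        assert len(df) == 20
        assert df["strain"].nunique() == 17

    def test_known_record_values(self):
        df = make_screen_fixture()
        row = df[(df.strain == "IFM 62632") & (df.virus_abbrev == "AfuPmV1")]
        assert len(row) == 1
        r = row.iloc[0]
        assert r.n_segments == 4 and r.genome_type == "dsRNA" and r.method == "AGE"
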