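"""Cognate-segment grouping: terminal-word extraction, similarity scores
and single-linkage partitioning against a brute-force closure oracle."""

import numpy as np
import pytest
from Bio.Seq import Seq

from fldskit.grouping import (
    extract_termini,
    group_segments,
    terminal_similarity,
)
from fldskit.simulate import generate_genome, random_terminal_words
from fldskit.termini import GenomeSegment

from conftest import make_spec


def seg(segment_id, sequence, strain="S1", full=True, polya=False):
    return GenomeSegment(
        segment_id=segment_id,
        host_strain=strain,
        sequence=sequence,
        has_5p_terminus=full,
        has_3p_terminus=full,
        polya_3p=polya,
        completeness="full_length" if full else "partial",
    )


def random_segment(rng, segment_id, w5, w3, interior=400, **kw):
    body = "".join(rng.choice(list("ACGT"), size=interior))
    return seg(segment_id, w5 + body + w3, **kw)


class TestExtractTermini:
    def test_words_are_sequence_extremes(self):
        s = seg("a", "ACGT" + "G" * 992 + "TTGA")
        assert extract_termini(s, window=4) == ("ACGT", "TTGA")

    def test_polya_trimmed_before_three_prime_word(self):
        s = seg("a", "ACGT" + "G" * 100 + "GCGC" + "A" * 12, polya=True)
        assert extract_termini(s, window=4)[1] == "GCGC"

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="shorter than window"):
            extract_termini(seg("a", "ACGTACGT"), window=20)

    def test_synthetic_words_match_spec(self):
        spec = make_spec(lengths=(1500, 900), seed=21, architecture="none")
        segs, _ = generate_genome(spec)
        for s in segs:
            gseg = seg(s.segment_id, s.sequence)
            w5, w3 = extract_termini(gseg, window=20)
            assert w5 == spec.terminal_word_5p
            assert w3 == spec.terminal_word_3p


class TestTerminalSimilarity:
    def test_identical_words_score_one(self):
        rng = np.random.default_rng(0)
        w5, w3 = random_terminal_words(rng)
        a = random_segment(rng, "a", w5, w3)
        b = random_segment(rng, "b", w5, w3)
        sim = terminal_similarity(a, b)
        assert sim.combined == 1.0

    def test_hand_counted_mixed_score(self):
        # 5' identical, 3' word with exactly 4/20 mismatches -> (1.0+0.8)/2
        rng = np.random.default_rng(1)
        w5, w3 = random_terminal_words(rng)
        w3_mut = list(w3)
        for i in (2, 7, 11, 16):
            w3_mut[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[w3_mut[i]]
        a = random_segment(rng, "a", w5, w3)
        b = random_segment(rng, "b", w5, "".join(w3_mut))
        sim = terminal_similarity(a, b)
        assert sim.score_5p == 1.0
        assert sim.score_3p == pytest.approx(0.8)
        assert sim.combined == pytest.approx(0.9)

    def test_random_words_score_near_chance(self):
        rng = np.random.default_rng(2)
        scores = []
        for _ in range(1000):
            a = random_segment(rng, "a", *random_terminal_words(rng), interior=10)
            b = random_segment(rng, "b", *random_terminal_words(rng), interior=10)
            scores.append(terminal_similarity(a, b).combined)
        # reverse-orientation maximisation lifts the mean slightly above 1/4
        assert 0.2 < np.mean(scores) < 0.33

    def test_reverse_complement_orientation_recovered(self):
        rng = np.random.default_rng(3)
        w5, w3 = random_terminal_words(rng)
        a = random_segment(rng, "a", w5, w3)
        b_fwd = random_segment(rng, "b", w5, w3)
        b_rc = seg("b", str(Seq(b_fwd.sequence).reverse_complement()))
        sim = terminal_similarity(a, b_rc)
        assert sim.combined == 1.0
        assert sim.orientation == "reverse"

    def test_partial_segment_rejected(self):
        rng = np.random.default_rng(4)
        a = random_segment(rng, "a", *random_terminal_words(rng))
        b = random_segment(rng, "b", *random_terminal_words(rng), full=False)
        with pytest.raises(ValueError, match="partial"):
            terminal_similarity(a, b)


def partition(assemblies):
    return frozenset(frozenset(a.member_segments) for a in assemblies)


def brute_force_components(segments, threshold, window=20):
    """Oracle: transitive closure of the thresholded similarity graph."""
    ids = [s.segment_id for s in segments]
    by_id = {s.segment_id: s for s in segments}
    adj = {i: set() for i in ids}
    for i in ids:
        for j in ids:
            if i < j:
                sim = terminal_similarity(by_id[i], by_id[j], window)
                if sim.combined >= threshold:
                    adj[i].add(j)
                    adj[j].add(i)
    seen, comps = set(), []
    for i in ids:
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return frozenset(comps)


class TestGroupSegments:
    def family(self, rng, n, prefix, **kw):
        w5, w3 = random_terminal_words(rng)
        return [
            random_segment(rng, f"{prefix}{i}", w5, w3, **kw) for i in range(n)
        ]

    def test_four_shared_segments_one_assembly(self):
        rng = np.random.default_rng(5)
        out = group_segments(self.family(rng, 4, "x"))
        assert len(out) == 1 and out[0].n_segments == 4

    def test_co_infection_two_word_families(self):
        rng = np.random.default_rng(6)
        segs = self.family(rng, 3, "x") + self.family(rng, 1, "y")
        out = group_segments(segs)
        assert sorted(a.n_segments for a in out) == [1, 3]

    def test_singleton(self):
        rng = np.random.default_rng(7)
        out = group_segments(self.family(rng, 1, "x"))
        assert len(out) == 1 and out[0].n_segments == 1

    def test_partition_property_and_permutation_invariance(self):
        rng = np.random.default_rng(8)
        segs = (
            self.family(rng, 4, "x") + self.family(rng, 2, "y")
            + self.family(rng, 1, "z")
        )
        out = group_segments(segs)
        members = [m for a in out for m in a.member_segments]
        assert sorted(members) == sorted(s.segment_id for s in segs)
        shuffled = list(segs)
        rng.shuffle(shuffled)
        assert partition(group_segments(shuffled)) == partition(out)

    def test_matches_brute_force_closure(self):
        rng = np.random.default_rng(9)
        segs = []
        for k in range(5):
            segs += self.family(rng, k + 1, f"f{k}_")
        assert len(segs) <= 20
        got = partition(group_segments(segs, threshold=0.8))
        assert got == brute_force_components(segs, threshold=0.8)

    def test_partial_segments_become_incomplete_singletons(self):
        rng = np.random.default_rng(10)
        segs = self.family(rng, 2, "x")
        segs.append(random_segment(rng, "p0", *random_terminal_words(rng),
                                   full=False))
        out = group_segments(segs)
        partial = [a for a in out if not a.complete]
        assert len(partial) == 1 and partial[0].member_segments == ["p0"]

    def test_mixed_strains_rejected(self):
        rng = np.random.default_rng(11)
        a = random_segment(rng, "a", *random_terminal_words(rng), strain="S1")
        b = random_segment(rng, "b", *random_terminal_words(rng), strain="S2")
        with pytest.raises(ValueError, match="strains"):
            group_segments([a, b])
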