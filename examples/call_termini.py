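"""Call genome termini on a simulated contig from its read-end pileup.

Terminal-complete dsRNA reads have alignment boundaries exactly at the
genome ends; the caller accepts an end when strictly more than
min_support (default 10) reads share that boundary, or when the 3' end
carries a polyA tail.
"""

import numpy as np

from fldskit import Contig, VirusSpec, call_contig
from fldskit.simulate import (
    generate_genome,
    random_terminal_words,
    simulate_flds_reads,
)

w5, w3 = random_terminal_words(np.random.default_rng(2))
spec = VirusSpec(
    virus_id="DemoV.strainA", host_strain="strainA",
    n_segments=1, segment_lengths=[1500],
    terminal_word_5p=w5, terminal_word_3p=w3,
    polya_len=15, rdrp_architecture="complete", seed=2,
)
segments, _ = generate_genome(spec)
reads, alignments = simulate_flds_reads(
    segments, depth=30, read_len=150, seed=2, terminal_reads_per_end=15
)

seg = segments[0]
contig = Contig(seg.segment_id, seg.sequence, "strainA")
c5, c3, genome_seg = call_contig(contig, alignments)

print(f"contig {seg.segment_id} ({len(seg.sequence)} nt, "
      f"{len(alignments)} aligned reads)")
for call in (c5, c3):
    print(f"  {call.side} end at {call.coordinate}: support={call.support} "
          f"reads, polyA={call.polya} -> called={call.called}")
print(f"  completeness: {genome_seg.completeness}")
print("\nBoth extremities exceed the 'more than 10 reads' rule (and the 3'")
print("end also shows the polyA tail), so the contig is a full-length genome.")
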