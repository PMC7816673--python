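# Methods

`fldskit` implements the downstream analysis of a terminal-complete
dsRNA virome screen.  Terminal-complete dsRNA sequencing (FLDS —
fragmented and primer-ligated dsRNA sequencing) ligates adapters to
sheared dsRNA before cDNA synthesis, so sequencing reads extend to the
exact 5'/3' ends of each viral RNA.  That property supports three
inferences that ordinary RNA-seq cannot make reliably: where a genome
segment ends, whether a contig is a complete segment, and which segments
belong to the same multipartite virus.  This note records the models,
parameters and design choices behind each stage.

## Terminus calling

Evidence is the pileup of read-alignment boundaries on a contig: a
start-count vector (reads beginning at each position) and an end-count
vector (reads whose last aligned base is each position).  A contig
extremity is called a genome terminus when

* the boundary count at the extremity is **strictly greater** than
  `min_support` (default 10, i.e. "more than ten reads": support 11
  calls, support 10 does not), or
* on the 3' side only, the contig ends in at least `polya_min`
  (default 8) consecutive A.

A contig with both ends called is classified `full_length`, otherwise
`partial`.  Calls are evaluated only at contig extremities; interior
boundary pileups above `min_support` are logged as warnings (possible
mis-assembly) but never become calls.  The boundary-coincidence
criterion relies on the assembler's consensus already enforcing per-base
agreement among the stacked read ends; a stricter per-base check would
need the read sequences and is not the default.  The polyA rule applies
to the 3' side only, and `polya_min = 8` is this package's choice — the
rule it implements only requires "a polyA sequence".  When polyA alone
supports a 3' call, the reported coordinate is still the contig
extremity and the read support count is reported as observed (possibly
0).

## Cognate-segment grouping

The segments of one multipartite virus share conserved 5' and 3'
terminal sequences.  For each full-length segment the 5' and 3' terminal
words of `window` nt (default 20) are extracted, after trimming a
flagged 3' polyA tail.  Pairwise similarity is the ungapped identity
fraction of the equal-length words; the combined score is the arithmetic
mean of the 5' and 3' scores.  Because deposited strands can differ,
each pair is also scored with one segment reverse-complemented (whose 5'
word is then the reverse complement of the other's 3' word) and the
better orientation is used and recorded.

Within one host strain, segments are grouped by single-linkage
clustering: any pair with combined score ≥ `threshold` (default 0.8) is
linked, and connected components become virus assemblies.  With
`require_both`, both the 5' and 3' scores must individually reach the
threshold.  Partial segments are passed through as singleton assemblies
flagged incomplete.  Output is deterministic: members ordered by
descending length then id, assemblies by their longest member.

Window 20 nt and threshold 0.8 are package defaults validated on
synthetic data; the source screening procedure judged terminal
similarity by inspection of terminal-region alignments without
publishing a numeric criterion.  Two random 20-nt word pairs score
about 0.25 on average (≈0.27 after maximizing over orientation), so the
0.8 threshold separates conserved from chance similarity by a wide
margin at this window size.  Gapped comparison of terminal words is
deliberately out of scope: the conserved words this method exploits
align without gaps.

## ORF prediction and RdRp motif architecture

ORFs are all maximal ATG-to-stop reading frames of at least `min_aa`
codons (default 100) on both strands and all three frames.  Two genetic
codes are supported: `standard` (translation table 1) and `mold_mito`
(table 4, TGA read as tryptophan) — relevant for mitochondrially
replicating viruses.  Coordinates are 0-based half-open on the reported
strand, covering start codon through last sense codon.

The RdRp catalytic core carries five conserved motifs in canonical order
F < A < B < C < D, with motif C containing the near-universal GDD triad.
Profiles are shipped as degenerate amino-acid consensus strings with an
exact-match anchor triplet and a mismatch budget (default 2) over the
remaining positions (`src/fldskit/data/rdrp_motifs.tsv`).  The A-motif
core (STDWESATD) and C-motif core (GDDEI) follow published narnavirus
consensus; the F, B and D patterns are this package's own transcription
of typical narnavirus conservation and are documented as such in the
profile file.  They are deliberately strict — built for recognizing
consensus-bearing sequences (as the simulator emits) rather than remote
homology search, for which profile HMMs would be the right tool.

Scanning assigns motifs left to right: for each label, the acceptable
match with the fewest mismatches (ties: leftmost) starting at or after
the previous assigned motif's end is taken; an absent label does not
advance the cursor.  Emitted hits are therefore always in canonical
order.  On 1,000 shuffled length-matched ORFs the full five-motif
architecture occurs in far less than 1% of cases (the anchor triplet
must match exactly, ≈20⁻³ per position per motif).

Per virus assembly the architecture is classified as:

* `complete` — one ORF carries all five motifs;
* `split` — one ORF carries F, A, B (and neither C nor D), and an ORF on
  a **different** member segment carries C and D with the C hit starting
  within the first `n_term_fraction` (default 0.4) of that ORF — the
  divided-RdRp signature;
* `partial` — F, A, B present with no qualifying C/D pair anywhere;
* `absent` — otherwise.

The N-terminal fraction of 0.4 is a package default (config-exposed);
the phenomenon it encodes is only described qualitatively as the
"N-terminal region" of the cognate ORF.  Classification is invariant
under reverse-complementing every segment, since ORFs are predicted on
both strands.

## OTU and species demarcation

RdRp-encoding segments sharing **more than** 90% nucleotide identity
form one OTU (single linkage, strict inequality — a pair at exactly
90.0% stays separate); an OTU whose representative (longest member)
shares more than 95% identity with a reference sequence is recognized as
that species, otherwise it is novel.  Identity is computed from a global
pairwise alignment (match +1, mismatch −1, gap open −2, gap extend −1)
as identities divided by alignment columns, gap columns included;
`denominator="shorter"` switches to the shorter-sequence denominator.
Each pair is scored in both relative orientations and the larger
identity is used.  The alignment mode and denominator are package
decisions — the demarcation criterion they implement states only the
percentage.  Assemblies without an RdRp carrier (no F/A/B ORF) cannot
enter the identity clustering and are assigned singleton OTUs;
non-RdRp segments inherit their assembly's OTU.

## Screening statistics

The tally over a strain-virus record table computes: per-host-species
positive strain counts and frequencies (rounded half-up to 1 decimal),
the AGE-detectable strain count and its fraction of all screened
strains, total records and distinct strains, distinct species groups and
the novel subset, the segmented-record breakdown (≥2 segments), and the
segmented fraction of complete records (rounded half-up to an integer).
A record counts as *complete* when its full genome sequence was
determined; a record whose termini were not fully resolved but whose
sequence was obtained still counts (the packaged fixture carries both
flags separately, and with it 8 of 19 complete records are segmented,
i.e. 42%).

## Synthetic data: what it emulates and what it does not

The simulator is the package's test instrument.  It emulates the
features the analysis logic depends on: conserved terminal words shared
verbatim within a virus (random 20-nt words per species; the 3' word is
drawn to not end in A so a polyA tail stays distinguishable), optional
15-nt polyA tails, uniform random interiors, planted ORFs with motif
consensus strings inserted at fixed offsets (an in-frame stop is planted
directly upstream of each ORF start so the predicted ORF is maximal and
coordinates match truth), co-infection, and — the defining property —
reads whose alignment boundary falls exactly on each genome end
(`terminal_reads_per_end`, default 15, with fragment lengths varying
between half and full read length), on top of `round(depth·L/read_len)`
uniformly placed reads.

It does **not** emulate: sequencing errors beyond an optional uniform
substitution rate (default 0), assembly errors or chimeras (contigs are
emitted error-free; de novo assembly is upstream of this package's
scope), rRNA contamination, real codon usage or motif divergence
(inserted motifs are exact consensus), or terminal-word divergence
within a virus.  Passing the synthetic recovery tests therefore shows
the *logic* is correct under the stated evidence model, not that the
default thresholds are optimal for noisy real libraries.

The built-in study (`default_study`) simulates 10 host strains carrying
12 virus species in 13 residencies: genome sizes 900–2,400 nt, 1–4
segments per virus, two co-infected strains (2 and 3 viruses), one
split-RdRp virus, one partial and one motif-less virus, three polyA
viruses, and one species resident in two strains (so the OTU step has a
non-trivial merge).  Sizes were chosen to exercise every code path while
a full run (including the all-pairs global alignment identity matrix)
completes in well under a minute.

## Numerical and degenerate-input choices

* Coordinates: 0-based half-open everywhere internally; SAM POS is
  converted on input, written back 1-based.
* Rounding of printed percentages: half away from zero (decimal
  arithmetic), matching printed-table conventions.
* Tie-breaks: motif hits by (mismatches, position); ORFs by (length
  desc, id); assemblies and OTUs by (longest member desc, id).  All
  outputs are deterministic under a fixed seed.
* Empty inputs: empty alignment lists give all-zero pileups; an empty
  record table gives zero counts and 0.0 frequencies; an empty reference
  set makes every OTU novel.
* U is normalized to T on input (cDNA convention); sequences are
  validated against {A,C,G,T,N}.

## Known limitations

Motif profiles are consensus strings, not position weight matrices or
HMMs; remote RdRp homologs will be missed.  Genome type (dsRNA vs
ssRNA) is metadata, not inferred — in the original screen it was
assigned by homology to known viruses, which is outside this package's
scope (as are BLAST/Pfam searches, phylogenetics and read QC).
Terminal-word grouping assumes the conserved words align without gaps.
Satellite RNAs versus genuine genome segments cannot be distinguished
by terminal similarity alone and are not adjudicated.
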