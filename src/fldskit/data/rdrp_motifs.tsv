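# RdRp catalytic-core motif profiles (narnavirus-flavoured consensus).
#
# Each row is a degenerate amino-acid consensus for one of the five
# conserved RdRp motifs (canonical order along the protein: F < A < B < C < D).
# `pattern` is matched by sliding over the ORF translation; `anchor` is the
# most conserved residue triplet and must match exactly inside the pattern;
# the remaining positions may diverge up to `max_mismatches`. An 'X' in a
# pattern matches any residue.
#
# The A-motif core STDWESATD and the C-motif core GDDEI (with the universal
# GDD catalytic triad) follow published narnavirus RdRp consensus; the F, B
# and D rows are this package's own transcription of typical narnavirus
# conservation (basic NTP-binding residues in F, the glycine-rich B turn,
# the D-motif lysine) and are deliberately conservative: they are intended
# for matching sequences that carry the consensus, not for sensitive remote
# homology search.
label	pattern	anchor	max_mismatches
F	RGKYKWGRL	KWG	2
A	STDWESATD	DWE	2
B	SQGSGFQNT	GSG	2
C	VYGDDEIVS	GDD	2
D	GLGAKSLEK	AKS	2
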