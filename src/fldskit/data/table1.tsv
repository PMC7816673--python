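strain	species	virus_name	virus_abbrev	n_segments	genome_type	method	novel	complete_sequence	termini_complete
IFM 62632	A. fumigatus	Aspergillus fumigatus polymycovirus 1	AfuPmV1	4	dsRNA	AGE	False	True	True
IFM 62632	A. fumigatus	Aspergillus fumigatus negative-stranded RNA virus 1	AfuNSRV1	1	ssRNA(-)	FLDS	True	True	False
IFM 63147	A. fumigatus	Aspergillus fumigatus chrysovirus	AfuCV	4	dsRNA	AGE	False	True	True
IFM 63147	A. fumigatus	Aspergillus fumigatus narnavirus 2	AfuNV2	3	ssRNA(+)	AGE	False	True	True
IFM 63147	A. fumigatus	Aspergillus fumigatus botourmiavirus 1	AfuBOV1	1	ssRNA(+)	FLDS	True	True	True
IFM 63431	A. fumigatus	Aspergillus fumigatus narnavirus 2	AfuNV2	3	ssRNA(+)	AGE	False	True	True
IFM 64916	A. fumigatus	Aspergillus fumigatus botourmiavirus 1	AfuBOV1	1	ssRNA(+)	AGE	True	True	True
IFM 62355	A. fumigatus	Aspergillus fumigatus mitovirus 1	AfuMV1	1	ssRNA(+)	Pooled FLDS	False	True	True
IFM 62629	A. fumigatus	Aspergillus fumigatus narnavirus 2	AfuNV2	3	ssRNA(+)	Pooled FLDS	False	True	True
IFM 63439	A. fumigatus	Aspergillus fumigatus RNA virus 1	AfuRV1	3	ssRNA(+)	Pooled FLDS	True	True	True
IFM 64779	A. fumigatus	Aspergillus fumigatus botourmiavirus 1	AfuBOV1	1	ssRNA(+)	Pooled FLDS	True	True	True
IFM 62627	A. lentulus	Aspergillus lentulus partitivirus 1	AlePV1	2	dsRNA	AGE	True	True	True
IFM 63547	A. lentulus	Aspergillus lentulus narnavirus 1	AleNV1	2	ssRNA(+)	AGE	True	True	True
IFM 64003	A. lentulus	Aspergillus lentulus non-segmented dsRNA virus 1	AleNdsRV1	1	dsRNA	AGE	True	True	True
IFM 64004	A. lentulus	Aspergillus lentulus non-segmented dsRNA virus 1	AleNdsRV1	1	dsRNA	AGE	True	True	True
IFM 65052	A. lentulus	Aspergillus lentulus totivirus 1	AleTV1	1	dsRNA	AGE	True	True	True
IFM 59502	A. pseudoviridinutans	Aspergillus pseudoviridinutans botourmiavirus 1	ApvBOV1	1	ssRNA(+)	Pooled FLDS	True	True	True
IFM 59503	A. pseudoviridinutans	Aspergillus pseudoviridinutans botourmiavirus 1	ApvBOV1	1	ssRNA(+)	Pooled FLDS	True	False	False
IFM 61377	A. pseudoviridinutans	Aspergillus pseudoviridinutans botourmiavirus 1	ApvBOV1	1	ssRNA(+)	Pooled FLDS	True	True	True
IFM 61378	A. pseudoviridinutans	Aspergillus pseudoviridinutans botourmiavirus 1	ApvBOV1	1	ssRNA(+)	Pooled FLDS	True	True	True
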