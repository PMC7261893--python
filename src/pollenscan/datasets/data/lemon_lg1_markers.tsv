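locus	lg	cm	class	p1_a1	p1_a2	p2_a1	p2_a2
CIBE6126	1	2.68	SSR	218	218	220	220
CIBE6147	1	14.39	SSR	214	214	293	293
CiC4827-01	1	20.54	SNP	A	A	G	G
1P3705568	1	32.48	SNP	A	A	G	G
EMA-M30	1	46.03	SNP	C	C	T	T
mCrCIR06B05	1	50.27	SSR	187	187	199	199
CIBE5720	1	58.15	SSR	320	320	333	333
MEST539	1	61.82	SSR	97	97	104	104
MEST001	1	70.60	SSR	171	171	187	187
CIC5950-02	1	91.37	SNP	G	G	A	A
TSC-C80	1	111.55	SNP	T	T	G	G
MEST431	1	119.00	SSR	331	331	348	348
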