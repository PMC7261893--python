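locus	lg	cm	class	p1_a1	p1_a2	p2_a1	p2_a2
CIBE6147	1	14.39	SSR	204	212	206	206
CIBE5720	1	58.69	SSR	325	341	329	337
TAA15	1	119.73	SSR	189	192	204	204
2P21022555	2	57.00	SNP	A	G	G	G
CX6F23	2	59.35	SSR	155	162	162	168
CIC3712-01	2	114.51	SNP	A	C	C	C
TAA41	2	160.74	SSR	148	154	154	160
MEST256	3	17.02	SSR	210	225	225	225
3P35931624	3	95.01	SNP	G	A	G	G
JI-TC01	3	109.67	SSR	333	352	333	342
C4P5278891	4	18.44	SNP	A	G	G	G
CI03G05	4	75.07	SSR	199	226	226	226
CI03D12a	4	90.06	SSR	251	261	280	280
MEST15	5	16.21	SSR	174	192	189	189
MEST88	5	57.05	SSR	112	118	104	112
mCrCIR06A12	5	93.20	SSR	95	102	95	95
CI07E12	5	95.43	SSR	118	124	118	118
MEST191	6	10.79	SSR	241	244	235	241
MEST488	6	68.39	SSR	126	140	126	126
CIBE6256	6	84.49	SSR	176	190	174	192
MEST107	7	8.89	SSR	175	182	175	175
MEST202	7	20.60	SSR	157	169	169	172
CIC3674-02	7	23.56	SNP	A	G	G	G
CI07C07	7	98.01	SSR	227	240	238	240
CI07B05	8	33.17	SSR	202	222	220	222
CIC1208-01	8	57.78	SNP	A	G	G	G
mCrCIR02G02	8	59.15	SSR	112	122	116	122
CI02B07	9	0.01	SSR	160	162	162	170
CIC5087-02	9	15.88	SNP	A	T	T	T
MEST308	9	50.41	SSR	241	260	260	260
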