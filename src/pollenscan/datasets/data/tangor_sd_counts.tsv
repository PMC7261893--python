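locus	lg	cm	pollen_a1	pollen_a2	pollen_chi2	pollen_p	progeny_a1	progeny_a2	progeny_chi2	progeny_p
CIBE6147	1	14.39	21	26	0.532	0.466	40	46	0.419	0.518
CIBE5720	1	58.69	27	21	0.750	0.387	41	45	0.186	0.666
TAA15	1	119.73	30	17	3.596	0.058	41	45	0.186	0.666
2P21022555	2	57.00	15	32	6.149	0.013	7	79	60.279	0.000
CX6F23	2	59.35	17	31	4.083	0.043	13	73	41.860	0.000
CIC3712-01	2	114.51	16	30	4.261	0.039	19	67	26.791	0.000
TAA41	2	160.74	21	27	0.750	0.387	52	34	3.767	0.052
MEST256	3	17.02	26	20	0.783	0.376	49	37	1.674	0.196
3P35931624	3	95.01	23	23	0.000	1.000	47	39	0.744	0.388
JI-TC01	3	109.67	23	22	0.022	0.882	42	44	0.047	0.829
C4P5278891	4	18.44	26	22	0.333	0.564	48	38	1.163	0.281
CI03G05	4	75.07	23	22	0.022	0.881	43	43	0.000	1.000
CI03D12a	4	90.06	25	21	0.348	0.555	41	45	0.186	0.666
MEST15	5	16.21	20	25	0.556	0.456	47	39	0.744	0.388
MEST88	5	57.05	31	16	4.787	0.029	40	46	0.419	0.518
mCrCIR06A12	5	93.20	24	23	0.021	0.884	38	48	1.163	0.280
CI07E12	5	95.43	25	21	0.348	0.555	42	44	0.047	0.829
MEST191	6	10.79	22	23	0.022	0.881	49	37	1.674	0.196
MEST488	6	68.39	25	20	0.556	0.456	50	36	2.279	0.131
CIBE6256	6	84.49	17	28	2.689	0.101	40	46	0.419	0.518
MEST107	7	8.89	24	23	0.021	0.884	4	82	70.744	0.000
MEST202	7	20.60	24	21	0.200	0.655	86	0	86.000	0.000
CIC3674-02	7	23.56	21	26	0.532	0.466	85	1	82.047	0.000
CI07C07	7	98.01	24	23	0.021	0.884	49	37	1.674	0.196
CI07B05	8	33.17	27	19	1.391	0.238	40	46	0.419	0.518
CIC1208-01	8	57.78	24	24	0.000	1.000	42	44	0.047	0.829
mCrCIR02G02	8	59.15	24	22	0.087	0.768	47	39	0.744	0.388
CI02B07	9	0.01	22	25	0.191	0.662	38	48	1.163	0.281
CIC5087-02	9	15.88	21	24	0.200	0.655	45	41	0.186	0.666
MEST308	9	50.41	22	25	0.191	0.662	47	39	0.744	0.388
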