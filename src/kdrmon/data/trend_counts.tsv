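location	year	group	n	LL	LF	FF	MM	MI	II
Boone	2019	pre	120	51	69	0	92	28	0
Boone	2019	post	47	4	35	8	31	16	0
Kanawha	2019	pre	120	0	102	18	113	7	0
Kanawha	2019	post	103	1	79	23	71	32	0
Sutherland	2019	pre	115	25	90	0	81	34	0
Sutherland	2019	post	95	0	95	0	66	29	0
All	2019	pre	355	76	261	18	286	69	0
All	2019	post	245	5	209	31	168	77	0
Nashua	2020	pre	110	61	47	2	98	12	0
Nashua	2020	post	38	0	38	0	0	38	0
Sutherland	2020	pre	110	14	10	86	95	15	0
Sutherland	2020	post	95	1	40	54	85	10	0
All	2020	pre	220	75	57	88	193	27	0
All	2020	post	133	1	78	54	85	48	0
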