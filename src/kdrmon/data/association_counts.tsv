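location	year	insecticide	group	n	LLMM	LLMI	LLII	LFMM	LFMI	LFII	FFMM	FFMI	FFII
Boone	2019	bifenthrin	moribund	32	2	10	0	19	1	0	0	0	0
Boone	2019	bifenthrin	survivor	8	1	2	0	5	0	0	0	0	0
Kanawha	2019	bifenthrin	moribund	29	0	0	0	28	0	0	1	0	0
Kanawha	2019	bifenthrin	survivor	11	0	0	0	8	1	0	2	0	0
Sutherland	2019	bifenthrin	moribund	37	5	1	0	27	4	0	0	0	0
Sutherland	2019	bifenthrin	survivor	2	0	0	0	0	2	0	0	0	0
Darwin	2019	bifenthrin	moribund	20	4	3	0	7	3	0	3	0	0
Darwin	2019	bifenthrin	survivor	17	0	1	0	9	6	0	1	0	0
All	2019	bifenthrin	moribund	118	11	14	0	81	8	0	4	0	0
All	2019	bifenthrin	survivor	38	1	3	0	22	9	0	3	0	0
Boone	2019	lambda-cyhalothrin	moribund	40	12	3	0	23	2	0	0	0	0
Boone	2019	lambda-cyhalothrin	survivor	0	0	0	0	0	0	0	0	0	0
Kanawha	2019	lambda-cyhalothrin	moribund	35	0	0	0	34	0	0	1	0	0
Kanawha	2019	lambda-cyhalothrin	survivor	5	0	0	0	1	2	0	2	0	0
Sutherland	2019	lambda-cyhalothrin	moribund	15	5	1	0	5	4	0	0	0	0
Sutherland	2019	lambda-cyhalothrin	survivor	22	3	2	0	8	9	0	0	0	0
Darwin	2019	lambda-cyhalothrin	moribund	20	4	6	0	8	1	0	1	0	0
Darwin	2019	lambda-cyhalothrin	survivor	20	1	5	0	5	9	0	0	0	0
All	2019	lambda-cyhalothrin	moribund	110	21	10	0	70	7	0	2	0	0
All	2019	lambda-cyhalothrin	survivor	47	4	7	0	14	20	0	2	0	0
Nashua	2020	bifenthrin	moribund	38	27	0	0	9	2	0	0	0	0
Nashua	2020	bifenthrin	survivor	0	0	0	0	0	0	0	0	0	0
Sutherland	2020	bifenthrin	moribund	20	0	0	0	0	0	0	20	0	0
Sutherland	2020	bifenthrin	survivor	18	0	1	0	0	0	0	17	0	0
All	2020	bifenthrin	moribund	58	27	0	0	9	2	0	20	0	0
All	2020	bifenthrin	survivor	18	0	1	0	0	0	0	17	0	0
Nashua	2020	lambda-cyhalothrin	moribund	29	17	1	0	10	1	0	0	0	0
Nashua	2020	lambda-cyhalothrin	survivor	8	3	0	0	4	0	0	1	0	0
Sutherland	2020	lambda-cyhalothrin	moribund	33	1	0	0	3	0	0	29	0	0
Sutherland	2020	lambda-cyhalothrin	survivor	3	0	0	0	0	0	0	3	0	0
All	2020	lambda-cyhalothrin	moribund	62	18	1	0	13	1	0	29	0	0
All	2020	lambda-cyhalothrin	survivor	11	3	0	0	4	0	0	4	0	0
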