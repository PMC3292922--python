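# Curated catalog of published genetic screens for modifiers of neurodegeneration models.
# One row per study; disease_models uses the closed code set {P, S, T, SOD, Abeta}.
study_id	organism	disease_models	construct	screen_type	n_reported	n_orthologues_expected	reference	provenance
1	worm	P	Htt-Q0, Q24, Q33, Q35, and Q40	Genome-wide RNAi	186	186	B10	catalog row 1
2	worm	SOD	G85R SOD	Genome-wide RNAi	81	81	B11	catalog row 2
3	worm	S	WT alpha-synuclein	Genome-wide RNAi	82	82	B9	catalog row 3
4	worm	T	Tau P301L and V337M	Genome-wide RNAi	75	75	B14	catalog row 4
5	worm	S	WT alpha-synuclein	Hypothesis-driven RNAi	20	20	B65	catalog row 5
6	worm	P	Htt-Q150	Candidate genes	12	12	B37	catalog row 6
7	worm	S	WT alpha-synuclein	Systematic RNAi screen	11	11	B68	catalog row 7
8	worm	P	Htt-Q128	Candidate genes	4	4	B13	catalog row 8
9	worm	Abeta	Abeta 1-42	Candidate genes	2	2	B69	catalog row 9
10	worm	T	Tau P301L and V337M	Forward genetic	2	2	B70	catalog row 10
11	worm	T	Tau V337M	Candidate genes	2	2	B71	catalog row 11
12	worm	P	Htt-Q32, Q40, Q56, Q79	Candidate genes	2	2	B72	catalog row 12
13	worm	P	Htt-Q2 and Q150	Candidate genes	1	1	B12	catalog row 13
14	yeast	P and S	Htt-Q20, Htt-Q53, A53T alpha-synuclein	Genome-wide genetic	138	41	B24	catalog row 14
15	yeast	S	alpha-synuclein	Selected genetic screen	77	20	B73	catalog row 15
16	yeast	Abeta	Abeta 1-42	Genome-wide genetic	40	11	B60	catalog row 16
17	yeast	P	Htt-Q103	Genome-wide loss-of-function suppressor	30	5	B50	catalog row 17
18	yeast	S	WT alpha-synuclein	Genome-wide overexpression	22	7	B58	catalog row 18
19	yeast	S	WT alpha-synuclein	Candidate genes	5	1	B59	catalog row 19
20	fly	T	Tau V337M	Large-scale genetic	30	14	B74	catalog row 20
21	fly	P	Htt-Q128	Protein interaction and selected genetic screen	32	34	B75	catalog row 21
22	fly	P	SCA1 82Q and Htt-Q128	Selective genetic modifier screen	24	20	B34	catalog row 22
23	fly	T	Tau V337M	Large-scale genetic	24	10	B76	catalog row 23
24	fly	P	Htt-Q127	Selective genetic modifier screen	10	2	B77	catalog row 24
25	fly	P	SCA3trQ78	Genome-wide screen	18	17	B63	catalog row 25
26	fly	P	SCA1 30Q and 82Q	Large-scale genetic	17	11	B78	catalog row 26
27	fly	P	Htt-Q127	Genome-wide screen	2	1	B79	catalog row 27
28	fly	S	A30P and A53T alpha-synuclein	Candidate gene	1	1	B80	catalog row 28
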