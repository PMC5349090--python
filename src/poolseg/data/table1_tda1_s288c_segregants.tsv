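segregant	PMA1	CEM1	ethyl_acetate_mg_per_l	sd
14s 26	TDA1(4)	TDA1(4)	11.6	1.2
14s 14	TDA1(4)	TDA1(4)	12.9	1.4
14s 23	TDA1(4)	TDA1(4)	13.8	0.5
14s 10	TDA1(4)	TDA1(4)	13.9	0.6
14s 4	TDA1(4)	TDA1(4)	14.9	0.3
14s 3	TDA1(4)	S288c	15.7	2.3
14s 32	TDA1(4)	S288c	15.9	0.4
14s 37	TDA1(4)	TDA1(4)	16.0	0.4
14s 39	S288c	S288c	16.2	1.4
14s 5	S288c	TDA1(4)	17.5	2.2
14s 8	TDA1(4)	TDA1(4)	17.6	0.3
14s 21	TDA1(4)	S288c	18.0	2.8
14s 18	TDA1(4)	S288c	18.4	0.2
14s 33	TDA1(4)	S288c	19.0	0.1
14s 19	S288c	TDA1(4)	19.2	2.4
14s 31	TDA1(4)	TDA1(4)	19.4	0.5
14s 35	S288c	TDA1(4)	19.5	2.8
14s 15	TDA1(4)	S288c	19.5	2.4
14s 44	TDA1(4)	S288c	19.7	0.2
14s 27	S288c	S288c	19.9	1.8
14s 6	S288c	S288c	20.0	0.7
14s 7	TDA1(4)	S288c	21.0	0.6
14s 42	TDA1(4)	S288c	21.0	0.9
14s 9	S288c	S288c	21.2	1.0
14s 24	S288c	TDA1(4)	21.4	1.0
14s 1	S288c	TDA1(4)	22.4	1.9
14s 25	TDA1(4)	S288c	22.8	3.3
14s 43	S288c	TDA1(4)	23.0	2.9
14s 30	S288c	TDA1(4)	23.3	1.7
14s 34	TDA1(4)	TDA1(4)	23.6	3.3
14s 17	TDA1(4)	S288c	23.8	0.3
14s 11	S288c	TDA1(4)	24.1	0.4
14s 12	TDA1(4)	S288c	25.4	1.5
14s 40	TDA1(4)	TDA1(4)	25.7	1.4
14s 28	S288c	TDA1(4)	27.9	2.2
14s 2	S288c	S288c	28.2	1.2
14s 41	S288c	TDA1(4)	28.2	1.7
14s 38	S288c	S288c	30.0	1.3
14s 13	S288c	S288c	30.5	1.5
14s 16	S288c	TDA1(4)	30.5	0.7
14s 29	S288c	S288c	30.8	0.1
14s 22	S288c	S288c	32.3	0.5
14s 20	S288c	TDA1(4)	34.1	1.5
14s 36	S288c	S288c	37.0	7.8
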