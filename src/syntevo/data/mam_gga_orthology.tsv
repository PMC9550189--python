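mam	mam_length_mbp	hsa	gga_segment	gga	complete	length_in_gga_mbp
1	414	2q-3pq-11qt-13-15a-21-Xp	1q	1	0	171
1	414	2q-3pq-11qt-13-15a-21-Xp	7	7	1	171
1	414	2q-3pq-11qt-13-15a-21-Xp	9	9	1	171
1	414	2q-3pq-11qt-13-15a-21-Xp	24	24	1	171
2	354	5pq-6pt-8q-9pq-18	2q	2	0	146
2	354	5pq-6pt-8q-9pq-18	Z	Z	0	146
3	309	2p-4-6p-8p-20	3pq	3	0	115
3	309	2p-4-6p-8p-20	4q	4	0	115
3	309	2p-4-6p-8p-20	20	20	1	115
3	309	2p-4-6p-8p-20	22	22	1	115
3	309	2p-4-6p-8p-20	Z	Z	0	115
4	269	1pq-6pq	1q	1	0	98
4	269	1pq-6pq	3q	3	0	98
4	269	1pq-6pq	8	8	1	98
4	269	1pq-6pq	21	21	0	98
4	269	1pq-6pq	23	23	0	98
4	269	1pq-6pq	25	25	1	98
4	269	1pq-6pq	26	26	1	98
5	274	1q-3p-7pq-10p-12pq-22b	1p	1	0	121
5	274	1q-3p-7pq-10p-12pq-22b	2pq	2	0	121
6	133	14-15b	5pq	5	0	50
6	133	14-15b	10	10	1	50
7	76	10q	6	6	1	26
8	52	11pq	5pq	5	0	19
9	44	16q-19q	11	11	1	18
10	42	7q-17pq	18	18	1	13
10	42	7q-17pq	27	27	1	13
11	41	3p-9q	12	12	1	16
12	38	5qt	13	13	1	15
13	35	1pt	21	21	0	10
13	35	1pt	23	23	0	10
14	31	12qt-22a	15	15	1	9
15	29	7pt-16p-17p	14	14	1	10
16	20	9qt	17	17	1	9
17	20	7q-17pq	19	19	1	9
18	9	19p	28	28	1	3
18	9	19p	30	30	1	3
19	6	19qt	32	32	1	0.12
X	54	Xpq	4p	4	0	13
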