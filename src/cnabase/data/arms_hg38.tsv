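chrom	arm	start	end
1	p	1	123400000
1	q	123400001	248956422
2	p	1	93900000
2	q	93900001	242193529
3	p	1	90900000
3	q	90900001	198295559
4	p	1	50000000
4	q	50000001	190214555
5	p	1	48800000
5	q	48800001	181538259
6	p	1	59800000
6	q	59800001	170805979
7	p	1	60100000
7	q	60100001	159345973
8	p	1	45200000
8	q	45200001	145138636
9	p	1	43000000
9	q	43000001	138394717
10	p	1	39800000
10	q	39800001	133797422
11	p	1	53400000
11	q	53400001	135086622
12	p	1	35500000
12	q	35500001	133275309
13	p	1	17700000
13	q	17700001	114364328
14	p	1	17200000
14	q	17200001	107043718
15	p	1	19000000
15	q	19000001	101991189
16	p	1	36800000
16	q	36800001	90338345
17	p	1	25100000
17	q	25100001	83257441
18	p	1	18500000
18	q	18500001	80373285
19	p	1	26200000
19	q	26200001	58617616
20	p	1	28100000
20	q	28100001	64444167
21	p	1	12000000
21	q	12000001	46709983
22	p	1	15000000
22	q	15000001	50818468
X	p	1	60600000
X	q	60600001	156040895
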