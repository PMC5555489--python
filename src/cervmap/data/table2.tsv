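linkage_group	n_loci	est_length_mb	cm_sexavg	cm_male	cm_female
1	1158	82.7	88.7	75.2	96.7
2	663	50.3	55.4	51.6	57.5
3	885	57.7	63.8	56.5	67.8
4	971	65.2	81.3	72.5	85.9
5	2039	137.9	126.8	119.7	130.8
6	723	52.6	59.6	52.8	63.5
7	660	51.7	64	60.6	65.7
8	860	58	62.1	54.4	66.7
9	1690	111.8	109.4	96.7	116.7
10	580	42.7	55.3	49.1	59.2
11	1547	107.1	101.3	81.7	112.1
12	1486	102.1	104.2	94	110
13	986	69.8	76.3	61.9	84.3
14	1113	82.2	85	79.4	88.2
15	1357	96.4	96.4	79.2	105.9
16	674	47	54.8	52.8	56.2
17	1059	68.3	67	59	71.5
18	1831	120.7	108	98.8	113.3
19	1476	101.9	99.3	85.1	107.3
20	1810	118.6	112.9	95.6	122.9
21	1236	84.1	85.5	69.7	94.6
22	882	62.3	65.2	55.2	71.1
23	1200	83.3	95.1	84.6	101.1
24	885	61.3	69.7	59.1	75.9
25	1066	72.1	76	66.9	80.6
26	633	41.7	51.7	50.9	52.2
27	886	62.5	62.2	47.8	70.7
28	938	65.5	64.7	60.3	67.2
29	969	67.2	65.9	59.2	69.4
30	1220	86.2	86.9	74.4	94
31	892	57.7	59.1	53.3	62.3
32	623	46.7	56.7	52.5	59.2
33	1220	80.4	80.8	70.3	86.9
34	1865	148.2	148.7	40	138.9
All	38083	2644.1	2739.7	2320.8	2906.3
All autosomal	36218	2495.7	2591.1	2280.8	2767.4
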