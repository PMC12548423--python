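# Published per-provirus mismatch summary for endogenous MMTV (Mtv) proviruses
# aligned to the Mtv1 reference (or, for the M. spretus group, a group consensus).
# Columns: raw substitution counts (GA, CT, AG, total over all classes), the
# printed %G>A-of-total at 1 decimal, printed query base composition, and run
# counts of 2-5 consecutive G>A. known_inconsistent=True marks rows whose printed
# %G>A does not follow from the printed counts under half-up rounding (Mtv55 is a
# rounding-boundary case: 32.35 printed as 32.3).
name	pct_G_printed	pct_A_printed	GA	CT	AG	total	pct_GA_printed	pct_decimals	runs2	runs3	runs4	runs5	known_inconsistent
Mtv21	10.8	41.8	943	57	34	1158	82.6	1	128	32	12	3	True
Mtv61	18.5	33.9	383	139	177	997	38.8	1	32	6	4	1	True
Mtv61-5p	21.0	33.0	107	70	131	479	22.3	1	3	0	0	0	False
Mtv61-3p	14.7	35.2	276	69	46	518	54.0	1	29	6	4	1	True
Mtv57	20.7	31.8	172	31	36	307	56.4	1	16	0	0	1	True
Mtv7	21.8	30.7	98	66	78	366	26.8	1	2	0	0	0	False
Mtv23	21.3	31.2	87	19	16	152	57.2	1	5	0	0	0	False
Mtv17	21.5	31.0	87	19	16	152	57.2	1	5	0	0	0	False
Mtv62	21.6	31.0	88	12	16	135	61.5	1	2	0	0	0	True
Mtv3	21.7	30.9	86	45	46	267	32.2	1	3	0	0	0	False
Mtv55	21.8	30.7	77	41	40	238	32.3	1	1	0	0	0	True
Mtv9	22.0	30.6	75	61	53	291	25.8	1	2	0	0	0	False
Mtv11	22.0	30.5	46	13	16	102	45.1	1	1	0	0	0	False
Mtv8	22.0	30.4	43	21	28	136	31.6	1	1	0	0	0	False
Mtv13	20.9	26.5	11	12	17	70	15.7	1	0	0	0	0	False
Mtv56	22.1	30.9	9	8	6	32	28.1	1	0	0	0	0	False
Mtv6	23.1	29.6	4	6	10	33	12.1	1	0	0	0	0	False
Mtv32	22.8	30.6	13	1	5	29	44.8	1	0	0	0	0	False
Mtv34	22.2	30.5	62	35	54	246	25.2	1	0	0	0	0	False
Mtv35	20.2	26.5	33	16	21	118	28.0	1	1	0	0	0	False
Mtv36	20.7	26.9	18	8	8	62	29.0	1	0	0	0	0	False
Mtv37	20.7	26.9	19	6	11	51	37.3	1	0	0	0	0	False
Mtv38	22.2	30.2	55	42	44	223	24.7	1	1	0	0	0	False
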