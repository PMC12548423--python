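# Published comparison of ultra-edited ERVs and exogenous retroviruses:
# alignment span (bp), G>A count, total mismatches, printed %G>A-of-mismatches
# at the precision given by pct_decimals, and printed G>A per 1,000 bp.
# known_inconsistent=True marks rows whose printed %G>A does not follow from
# the printed counts (IAPEz-int: 198/233 = 84.98, printed 85.34).
name	length	GA	total	pct_GA_printed	pct_decimals	GA_per_kb_printed	known_inconsistent
Mtv21	7924	957	1158	82.6	1	120.8	False
Mtv61	7923	387	997	38.8	1	48.8	False
Mtv61-3p	3450	280	518	54.1	1	81.2	False
TguERVl1_I-int	5486	392	475	82.53	2	71.5	False
TguLTRK1_1	6173	353	440	80.23	2	57.2	False
MuRRS-int	4657	199	225	88.44	2	42.7	False
IAPEz-int	6382	198	233	85.34	2	31.0	True
HERVK-int	5375	148	205	72.2	1	27.5	False
NICER2_Ra-int	7513	93	100	93	0	12.4	False
HIV-1_VAU	9330	679	722	94	0	72.8	False
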