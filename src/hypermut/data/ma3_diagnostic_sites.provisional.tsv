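# PROVISIONAL / SYNTHETIC stand-in for the diagnostic replacement sites that
# distinguish the mouse APOBEC3 alleles mA3-B6 and mA3-BALB.  The true residue
# identities at the 15 published diagnostic positions are not available in
# machine-readable form, so this file ships placeholder residues purely to
# exercise the haplotype engine; replace it with curated values before any
# biological use.  Columns are 1-based alignment columns of a translated
# alignment.
# allele_A_name=mA3-B6 allele_B_name=mA3-BALB
column	residue_A	residue_B
34	G	E
37	K	N
38	G	S
62	Q	R
80	V	I
109	L	F
134	V	A
135	Q	H
136	D	N
184	T	I
200	M	T
201	D	G
202	P	S
225	R	Q
237	T	A
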