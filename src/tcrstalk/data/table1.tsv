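tcr	trbv13_2	pdb_id	cdr3_seq	dist_a	dist_b	dist_c
D10	Y	1D9K	CASGGQGRAEQFF	4.81	5.73	5.40
172.10	Y	1U3H	CASGDAGGGYEQYF	4.98	5.28	4.90
2C	Y	2OI9	CASGGGGTLYF	5.12	5.25	4.85
HA1.7	N	1FYT	CASSSTGLPYGYTF	5.06	NA	4.82
AHIII 12.2	N	1LP9	CASSDWVSYEQYF	5.17	4.95	4.88
N15	N	1NFD	CASSLRWGDEQYF	4.55	NA	5.26
JM22	N	1OGA	CASSRSSYEQYF	4.59	6.04	4.96
1G4	N	2BNQ	CASSYVGNTGELFF	4.82	NA	4.98
KK50.4	N	2ESV	CASSQDRDTQYF	4.84	5.67	4.93
3A6	N	1ZGL	CASSLADRVNTEAFF	6.12	NA	5.60
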