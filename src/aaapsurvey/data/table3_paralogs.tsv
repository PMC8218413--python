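gene_a	gene_b	s_sites	n_sites	ka	ks	ka_ks	selection	dup_type	time_mya
CaANT1	CaANT2	304.25	970.75	0.16	0.57	0.29	purifying	tandem	40.96
CaANT2	CaANT3	305.00	976.00	0.05	0.12	0.40	purifying	tandem	8.53
CaANT1	CaANT3	304.83	970.17	0.15	0.57	0.26	purifying	tandem	40.59
CaLHT1	CaLHT3	313.75	1015.25	0.13	0.58	0.22	purifying	tandem	41.43
CaAAP1	CaAAP3	316.08	1015.92	0.07	0.14	0.50	purifying	tandem	10.37
CaANT1	CaANT4	303.58	971.42	0.11	0.82	0.14	purifying	segmental	58.87
CaAAP5	CaAAP6	351.08	1091.92	0.11	0.75	0.15	purifying	segmental	54.00
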