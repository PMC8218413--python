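name	iupac	description
ABRE	ACGTG	abscisic acid responsiveness (ABA-responsive element core)
ARE	AAACCA	anaerobic induction
LTR	CCGAAA	low-temperature responsiveness
MBS	CAACTG	MYB binding site, drought inducibility
TGACG-motif	TGACG	MeJA responsiveness (as-1 element half-site)
CGTCA-motif	CGTCA	MeJA responsiveness (reverse complement of TGACG)
TCA-element	CCATCTTTTT	salicylic acid responsiveness
GARE-motif	TCTGTTG	gibberellin responsiveness
AuxRR-core	GGTCCAT	auxin responsiveness
TC-rich_repeats	ATTTTCTTCA	defense and stress responsiveness
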