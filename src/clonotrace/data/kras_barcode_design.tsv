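codon_index	wildtype_codon	allowed_codons
9	GTT	GTT,GTC
10	GGA	GGA,GGG
11	GCT	GCT,GCC
15	GGC	GGC,GGT
16	AAG	AAG,AAA
17	AGC	AGC,AGT
18	GCC	GCC,GCT
19	TTG	TTG,TTA
20	ACG	ACG,ACA
21	ATA	ATA,ATT,ATC
22	CAG	CAG,CAA
23	CTA	CTA,CTG
24	ATT	ATT,ATC,ATA
25	CAG	CAG,CAA
26	AAT	AAT,AAC
27	CAC	CAC,CAT
28	TTT	TTT,TTC
29	GTG	GTG,GTA
30	GAT	GAT,GAC
31	GAA	GAA,GAG
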