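# Confirmed SNPs of the ingested probiotic strain relative to its reference genome.
# Coordinates are 1-based on the chromosome. coding_effect: nonsynonymous/synonymous/intergenic.
snp_id	replicon	pos	ref	alt	gene_id	coding_effect	aa_change	gene_name	product
SNP01	chromosome	63020	C	A	Gene0056	nonsynonymous	Q86H	HP	Transposase
SNP10	chromosome	695080	T	C	Gene0658	nonsynonymous	S194P	hcaR	Transcriptional activator for 3-phenylpropionic acid catabolism
SNP22	chromosome	1283071	A	G	Gene1205	nonsynonymous	L186S	HP	Hypothetical protein
SNP23	chromosome	1338981	A	C	Gene1257	nonsynonymous	D484E	ram2	Bacterial alpha-L-rhamnosidase 6 hairpin glycosidase
SNP27	chromosome	1589637	G	T	Gene1470	nonsynonymous	L827M	trePP	Trehalose 6-phosphate phosphorylase
SNP28	chromosome	1590767	T	G	Gene1470	nonsynonymous	D450A	trePP	Trehalose 6-phosphate phosphorylase
SNP32	chromosome	1861048	T	C	Gene1717	synonymous	T164T	yagU	Inner membrane protein response to acidic
SNP41	chromosome	2799363	A	G	Gene2601	synonymous	E328E	spa	Immunoglobulin G-binding protein
SNP43	chromosome	2854610	A	C	Gene2651	nonsynonymous	D202A	gor	Glutathione reductase
SNP46	chromosome	3007122	T	G	Gene2804	nonsynonymous	S41A	int4	Transposase
SNP47	chromosome	3007289	T	G	Gene2804	synonymous	A96A	int4	Transposase
SNP50	chromosome	3212834	T	G	Gene3003	nonsynonymous	F99L	ybhF	ABC transporter ATP-binding protein
SNP51	chromosome	3213000	G	T	Gene3003	nonsynonymous	V155L	ybhF	ABC transporter ATP-binding protein
SNP55	chromosome	3310964	C	T	Gene3110	nonsynonymous	G130S	tnp2PF3	Transposase
SNP56	chromosome	3311024	T	C	Gene3110	nonsynonymous	T110A	tnp2PF3	Transposase
SNP57	chromosome	3311155	A	C	Gene3110	nonsynonymous	V66G	tnp2PF3	Transposase
SNP58	chromosome	3311174	T	C	Gene3110	nonsynonymous	N60D	tnp2PF3	Transposase
SNP59	chromosome	3311468	G	A	Gene3111	synonymous	S60S	tnp2PF3	Transposase
SNP60	chromosome	3311545	T	C	Gene3111	nonsynonymous	K35E	tnp2PF3	Transposase
SNP61	chromosome	1976363	A	G	NA	intergenic	NA	NA	NA
SNP62	chromosome	1976367	G	T	NA	intergenic	NA	NA	NA
SNP71	chromosome	3271378	G	T	NA	intergenic	NA	NA	NA
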