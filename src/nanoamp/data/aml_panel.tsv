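name	gene	chrom	start	end	fwd_primer	rev_primer	pool	identity_pct	ins_pct	del_pct	sub_pct
CEBPA_ex1	CEBPA	chr19	33792118	33793481	GGAGGCACCGGAATCTCCTA	GGCCTGCCGGGTATAAAAGCTG	1	86.0	2.9	5.6	5.4
TP53_ex7-9	TP53	chr17	7576463	7577667	CAGGCTAGGCTAAGCTATGATGTTCCTTAGA	CTTGCCACAGGTCTCCCCAAGG	1	87.8	2.5	5.6	4.0
TP53_ex10-11	TP53	chr17	7572810	7574095	GTGCTTCTGACGCACACCTATTG	AACCATCTTTTAACTCAGGTACTGTGT	1	87.5	2.5	5.9	4.1
NPM1_ex11	NPM1	chr5	170837410	170837635	GTTAACTCTCTGGTGGTAGAATGAAAAATAGA	GATATCAACTGTTACAGAAATGAAATAAGACG	2	89.3	2.4	5.4	2.9
FLT3_ex14-15	FLT3	chr13	28607916	28608407	GGCAAACAGTAACCATTAAAAGGATGG	TTCCTCTATCTGCAGAACTGCCTA	2	88.5	3.3	4.6	3.6
FLT3_ex20	FLT3	chr13	28592521	28592740	CACAGTGAGTGCAGTTGTTTACCA	GTCATTCTTGACAGTGTGTTCACAG	2	90.2	2.7	3.4	3.7
IDH2_ex4	IDH2	chr15	90631713	90632029	CACAAAGTCTGTGGCCTTGTACT	GTTGAAAGATGGCGGCTGCA	2	88.8	2.3	5.4	3.6
TP53_ex2-4	TP53	chr17	7579204	7579986	GAAGCCAAAGGGTGAAGAGGAATCCC	AGGGTTGGAAGTGTCTCATGCTGGA	3	86.4	2.2	7.3	4.0
TP53_ex5-6	TP53	chr17	7578016	7578702	TTCAACTGTGCAATAGTTAAACCCAT	CTGAGGTGTAGACGCCAACTCTC	3	87.9	2.6	5.2	4.2
IDH1_ex4	IDH1	chr2	209113021	209113452	ATACAAGTTGGAAATTTCTGGGCCAT	CACTGCAGTTGTAGGTTATAACTATCCA	3	88.9	2.3	4.8	3.7
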