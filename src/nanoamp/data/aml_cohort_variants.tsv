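case	gene	chrom	pos	genotype	coding_change	aa_change	var_type	function	length	exon	minion	minion_vaf	s5	s5_vaf	sanger
AML#1	IDH1	chr2	209113113	G/A	c.394C	p.R132	SNV	missense	1	4	YES	48.9	YES	47.1	NE
AML#2	FLT3	chr13	28608329	A/C	c.1727T>G	p.L576R	SNV	missense	1	14	YES	14.4	YES	8.3	NE
AML#3	NPM1	chr5	170837547	-/TCTG	c.859_860insTCTG	p.W288fs*12	INDEL	FrameshiftInsertion	4	11	YES	35.3	YES	54.5	NE
AML#4	IDH1	chr2	209113113	G/A	c.394C	p.R132	SNV	missense	1	4	YES	16.9	YES	14.4	NE
AML#5	NPM1	chr5	170837547	-/TCTG	c.859_860insTCTG	p.W288fs*12	INDEL	FrameshiftInsertion	4	11	YES	56.5	YES	45.8	NE
AML#5	IDH2	chr15	90631934	C/T	c.419G	p.R140	SNV	missense	1	4	YES	32.4	YES	51.3	NE
AML#7	NPM1	chr5	170837547	-/TCTG	c.859_860insTCTG	p.W288fs*12	INDEL	FrameshiftInsertion	4	11	NO		YES	58.5	YES
AML#7	IDH2	chr15	90631934	C/A	c.419G	p.R140	SNV	missense	1	4	YES	38.6	YES	53.5	NE
AML#7	CEBPA	chr19	33792277	G/CT	c.1044delinsAG	p.S348fs	INDEL	FrameshiftInsertion	2	1	YES	15.4	NO		NO
AML#8	NPM1	chr5	170837547	-/TCTG	c.859_860insTCTG	p.W288fs*12	INDEL	FrameshiftInsertion	4	11	YES	33.3	YES	46.1	NE
AML#8	CEBPA	chr19	33793152	-/G	c.168dupC	p.E57fs	INDEL	FrameshiftInsertion	1	1	YES	44.3	NO		YES
AML#9	NPM1	chr5	170837547	-/TCTG	c.859_860insTCTG	p.W288fs*12	INDEL	FrameshiftInsertion	4	11	YES	31.0	YES	55.9	NE
AML#9	CEBPA	chr19	33792731	-/GCGGGT	c.589_590insACCCGC	p.H195_P196dup	INDEL	NonframeshiftInsertion	6	1	NO		YES	18.1	NO
AML#10	IDH2	chr15	90631934	C/T	c.419G	p.R140	SNV	missense	1	4	YES	16.1	YES	12.1	NE
AML#13	CEBPA	chr19	33792387	-/CTGCGTCTCCACGTTGCGCTGCTTGGC	c.933_934insGCCAAGCAGCGCAACGTGGAGACGCAG	p.A303_Q311dup	INDEL	NonframeshiftInsertion	27	1	YES	26.2	YES	38.9	NE
AML#13	CEBPA	chr19	33793082	-/C	c.238dupG	p.D80fs	INDEL	FrameshiftInsertion	1	1	YES	30.4	NO		YES
AML#14	CEBPA	chr19	33792381	-/CTT	c.939_940insAAG	p.K313dup	INDEL	NonframeshiftInsertion	3	1	YES	27.1	YES	48.7	NE
AML#14	CEBPA	chr19	33793174	CG/C	c.146delC	p.P49fs	INDEL	FrameshiftDeletion	1	1	YES	42.1	YES	57.5	NE
AML#14	CEBPA	chr19	33792729	G/A	c.592C>T	p.P198S	SNV	missense	1	1	NO		YES	16.2	NO
AML#15	CEBPA	chr19	33792729	G/A	c.592C>T	p.P198S	SNV	missense	1	1	NO		YES	14.8	NO
AML#16	NPM1	chr5	170837545	-/TGCA	c.861_862insTGCA	p.W288fs*12	INDEL	FrameshiftInsertion	4	11	YES	47.6	YES	46.6	NE
AML#16	IDH2	chr15	90631934	C/T	c.419G	p.R140	SNV	missense	1	4	YES	60.7	YES	53.8	NE
AML#17	NPM1	chr5	170837545	-/TGCA	c.861_862insTGCA	p.W288fs*12	INDEL	FrameshiftInsertion	4	11	YES	39.1	YES	57.6	NE
AML#17	FLT3	chr13	28592642	C/A	c.2503G	p.D835	SNV	missense	1	20	YES	49.0	YES	50.0	NE
AML#18	TP53	chr17	7577120	C/T	c.818G>A	p.R273H	SNV	missense	1	8	YES	78.5	YES	72.8	NE
AML#18	CEBPA	chr19	33792729	G/A	c.592C>T	p.P198S	SNV	missense	1	1	NO		YES	15.7	NO
AML#19	TP53	chr17	7577538	C/T	c.743G>A	p.R248Q	SNV	missense	1	7	YES	68.2	YES	63.1	NE
AML#20	TP53	chr17	7577082	C/T	c.856G>A	p.E286K	SNV	missense	1	8	YES	73.1	YES	79.1	NE
AML#21	TP53	chr17	7577094	G/A	c.844C>T	p.R282W	SNV	missense	1	8	YES	48.7	YES	49.1	NE
AML#21	TP53	chr17	7578475	G/C	c.455C>G	p.P152R	SNV	missense	1	5	YES	21.0	YES	11.5	NE
AML#21	CEBPA	chr19	33792731	-/GCGGGT	c.589_590insACCCGC	p.H195_P196dup	INDEL	NonframeshiftInsertion	6	1	NO		YES	25.2	NO
AML#22	TP53	chr17	7578413	C/T	c.517G>A	p.V173M	SNV	missense	1	5	YES	18.1	YES	45.3	NE
AML#22	TP53	chr17	7579715	AG/A	c.81del	p.E28Kfs*16	INDEL	FrameshiftDeletion	1	3	YES	45.0	YES	41.8	NE
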