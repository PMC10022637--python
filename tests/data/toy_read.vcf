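##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	s1	s2	s3
chr1	100	m1	A	T	.	.	.	GT	0/0	0/1	1/1
chr1	250	m2	G	C	.	.	.	GT	./.	1/1	0/0
chr1	300	m3	C	A,T	.	.	.	GT	0/1	0/2	1/1
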