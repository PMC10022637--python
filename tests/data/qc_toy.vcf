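##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	s01	s02	s03	s04	s05	s06	s07	s08	s09	s10
chr1	1000	miss10	A	T	.	.	.	GT	./.	0/0	0/1	1/1	0/0	0/1	1/1	0/0	0/1	1/1
chr1	2000	maf05	A	T	.	.	.	GT	0/1	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0
chr1	3000	mono	G	C	.	.	.	GT	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0
chr1	4000	miss20	G	T	.	.	.	GT	./.	./.	0/1	1/1	0/0	0/1	1/1	0/0	0/1	1/1
chr1	5000	ok1	A	C	.	.	.	GT	0/0	0/1	1/1	0/1	0/0	1/1	0/1	0/0	0/1	1/1
chr1	6000	ok2	T	G	.	.	.	GT	0/1	0/0	0/1	1/1	0/1	0/0	1/1	0/1	0/0	0/1
chr1	7000	ok3	C	A	.	.	.	GT	1/1	0/1	0/0	0/1	1/1	0/0	0/1	1/1	0/1	0/0
chr1	8000	ok4	G	A	.	.	.	GT	0/0	1/1	0/1	0/0	0/1	1/1	0/0	0/1	1/1	0/1
chr1	9000	ok5	A	G	.	.	.	GT	0/1	0/1	0/0	1/1	0/0	0/1	0/1	1/1	0/0	0/1
chr1	9500	ok6	C	T	.	.	.	GT	1/1	0/0	0/1	0/1	1/1	0/1	0/0	0/0	0/1	1/1
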