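# Consensus segment catalogue at the MECP2 locus, TSS-relative kb
# (positive = transcription direction). Derived from public multi-sample
# tracks: S = histone-PTM enrichment and H = hypomethylation (GSE17312,
# hg19 anchor chrX:153,363,188), A = DNase accessibility (GSE18927, hg19),
# B = ATAC accessibility (GSE211822, hg38 anchor chrX:154,097,717).
set	label	start_kb	end_kb	assembly
S	S1	-1.0	7.0	hg19
S	S2	13.0	15.0	hg19
S	S3	20.0	25.0	hg19
S	S4	32.0	42.0	hg19
S	S5	46.0	59.0	hg19
S	S6	61.0	72.0	hg19
S	S7	73.0	79.0	hg19
S	S8	83.0	87.0	hg19
S	S9	94.5	96.3	hg19
S	S10	112.0	117.0	hg19
S	S11	122.0	135.0	hg19
A	A1	-0.5	0.1	hg19
A	A2	0.4	0.8	hg19
A	A3	46.3	46.4	hg19
A	A4	50.9	51.3	hg19
A	A5	77.7	77.9	hg19
A	A6	83.8	84.0	hg19
A	A7	124.4	127.4	hg19
A	A8	144.1	144.4	hg19
A	A9	150.1	150.4	hg19
B	B1	-0.8	1.7	hg38
B	B2	50.8	51.6	hg38
B	B3	77.2	77.9	hg38
B	B4	83.8	85.6	hg38
B	B5	95.0	95.5	hg38
B	B6	124.7	127.7	hg38
B	B7	130.4	131.4	hg38
B	B8	144.1	144.3	hg38
B	B9	6.5	7.0	hg38
H	H1	-1.1	3.7	hg19
H	H2	4.6	5.4	hg19
H	H3	50.2	51.5	hg19
H	H4	77.1	78.7	hg19
H	H5	83.9	84.1	hg19
H	H6	124.2	129.4	hg19
H	H7	144.0	144.4	hg19
H	H8	147.5	150.0	hg19
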