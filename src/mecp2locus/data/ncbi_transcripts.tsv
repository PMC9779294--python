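# NCBI MECP2 (Gene ID: 4204) curated mRNA variant catalogue, transcribed from
# the RefSeq records as of 2022-10-15. NM_ accessions are reviewed RefSeq.
accession	source_db	product_isoform	review_status	evidence	biotype	tsl	cds_incomplete
NM_004992.4	NCBI	isoform 1	reviewed	RefSeq curated; translation initiates in exon 2	protein coding	-	-
NM_001110792.2	NCBI	isoform 2	reviewed	RefSeq curated; translation initiates in exon 1	protein coding	-	-
NM_001316337.2	NCBI	isoform 3	reviewed	RefSeq curated; shorter N-terminus than isoform 1	protein coding	-	-
NM_001369391.2	NCBI	isoform 3	reviewed	RefSeq curated	protein coding	-	-
NM_001369392.2	NCBI	isoform 3	reviewed	RefSeq curated	protein coding	-	-
NM_001369393.2	NCBI	isoform 3	reviewed	RefSeq curated	protein coding	-	-
NM_001369394.2	NCBI	isoform 3	reviewed	RefSeq curated	protein coding	-	-
NM_001386137.1	NCBI	isoform 4	reviewed	RefSeq curated; translation start within exon 4	protein coding	-	-
NM_001386138.1	NCBI	isoform 4	reviewed	RefSeq curated	protein coding	-	-
NM_001386139.1	NCBI	isoform 4	reviewed	RefSeq curated	protein coding	-	-
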