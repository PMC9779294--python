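# UniProt P51608 (MECP2_HUMAN) isoform catalogue with Ensembl cross-references,
# transcribed from the database records as of 2022-10-15.
accession	source_db	product_isoform	review_status	evidence	biotype	tsl	cds_incomplete	ensembl_transcript
P51608-1	UniProt/Ensembl	MeCP2E2	reviewed	Evidence at protein level	protein coding	1	-	ENST00000303391.11
P51608-2	UniProt/Ensembl	MeCP2E1	reviewed	Evidence at protein level	protein coding	1	-	ENST00000453960.7
B5MCB4	UniProt/Ensembl	-	unreviewed	Evidence at protein level	protein coding	5	-	ENST00000407218.5
A0A0D9SFX7	UniProt/Ensembl	-	unreviewed	Evidence at protein level	protein coding	3	-	ENST00000628176.2
C9JH89	UniProt/Ensembl	-	unreviewed	Evidence at protein level	protein coding	5	3prime	ENST00000415944.3
A0A1B0GTV0	UniProt/Ensembl	-	unreviewed	Evidence at protein level	protein coding	5	both	ENST00000637917.1
A0A0D9SEX1	UniProt/Ensembl	-	unreviewed	Evidence at protein level	protein coding	5	3prime	ENST00000630151.2
H7BY72	UniProt/Ensembl	-	unreviewed	Protein predicted	nonsense mediated decay	3	-	ENST00000369957.5
A0A6Q8PHQ3	UniProt/Ensembl	-	unreviewed	Protein predicted	nonsense mediated decay	-	-	ENST00000674996.1
A0A6Q8PF93	UniProt/Ensembl	-	unreviewed	Protein predicted	nonsense mediated decay	-	-	ENST00000675526.1
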