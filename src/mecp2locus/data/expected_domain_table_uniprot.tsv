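# Expected domain-completeness matrix for the synthetic UniProt-style panel.
# NLS1/NLS2 and the AT-hooks are absent from every panel isoform and are
# asserted separately rather than carried as rows.
row	B5MCB4_syn	A0A0D9SFX7_syn	C9JH89_syn	A0A1B0GTV0_syn	A0A0D9SEX1_syn	H7BY72_syn	A0A6Q8PHQ3_syn	A0A6Q8PF93_syn
Exon 1	✓	-	-	-	-	-	-	-
Exon 2	-	✓	✓	-	✓	C-term. incompl.	✓	✓
Exon 3	✓	✓	C-term. incompl.	-	C-term. incompl.	-	-	-
Exon 4	C-term. incompl.	C-term. incompl.	-	C-term. incompl., missing fragment inside	-	-	-	-
HMGD1	Possible different N-terminus	✓	C-term. incompl.	-	C-term. incompl.	C-term. incompl.	C-term. incompl.	C-term. incompl.
HMGD2	-	C-term. incompl.	-	-	-	-	-	-
MBD	C-term. incompl.	C-term. incompl.	-	N-term. and C-term. incompl.	-	-	-	-
aDBD	-	-	-	N-term. incompl.	-	-	-	-
TRD	-	-	-	N-term. incompl.	-	-	-	-
H3-M-T IS	✓	✓	-	-	-	-	-	-
NID	-	-	-	N-term. incompl.	-	-	-	-
TBL1XR1 IS	-	-	-	N-term. incompl.	-	-	-	-
WW-2 IS	-	-	-	-	-	-	-	-
CTDα	-	-	-	C-term. incompl.	-	-	-	-
CTDβ	-	-	-	-	-	-	-	-
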