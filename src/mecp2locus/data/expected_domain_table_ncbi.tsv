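# Expected domain-completeness matrix for the synthetic NCBI-style panel.
row	isoform1_E2_syn	isoform2_E1_syn	isoform3_syn	isoform4_syn
Exon 1	-	✓	-	-
Exon 2	✓	-	-	-
Exon 3	✓	✓	N-term. incompl.	-
Exon 4	✓	✓	✓	N-term. incompl.
HMGD1	✓	Possible different N-terminus	-	-
HMGD2	✓	✓	✓	-
MBD	✓	✓	N-term. incompl.	-
aDBD	✓	✓	✓	N-term. incompl.
TRD	✓	✓	✓	N-term. incompl.
NLS1	✓	✓	✓	-
NLS2	✓	✓	✓	✓
AT-hook 1	✓	✓	✓	-
AT-hook 2	✓	✓	✓	✓
H3-M-T IS	✓	✓	N-term. incompl.	-
NID	✓	✓	✓	✓
TBL1XR1 IS	✓	✓	✓	✓
WW-2 IS	✓	✓	✓	✓
CTDα	✓	✓	✓	✓
CTDβ	✓	✓	✓	✓
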