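# SYNTHETIC cis-regulatory element placements (TSS-relative kb, hg19 anchor).
# The genomic coordinates of the MECP2 F elements and promoter elements are
# not published as plain coordinates; these placements are synthetic fixtures
# consistent with the catalogued containment relations and can be replaced by
# user-supplied intervals.
name	role	start_kb	end_kb	assembly
universal enhancer	enhancer	-1.05	-0.80	hg19
distal promoter	promoter	-1.00	-0.85	hg19
weak silencer	silencer	-0.75	-0.55	hg19
silencer of astrocytoma	silencer	-0.50	-0.30	hg19
proximal promoter	promoter	-0.28	-0.12	hg19
core promoter	promoter	-0.10	0.00	hg19
F3	silencer	4.60	5.40	hg19
F11	enhancer	74.00	74.40	hg19
F13	silencer	75.00	75.35	hg19
F16	enhancer	95.05	95.45	hg19
F17	enhancer	112.80	113.30	hg19
F21	enhancer	125.00	126.00	hg19
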