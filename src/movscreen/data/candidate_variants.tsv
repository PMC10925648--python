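gene	transcript	cdna_hgvs	protein_hgvs	dbsnp	af_1000g	acmg_class_reported	acmg_tags	carriers	total	wild_type_length
SLC25A5	NM_001152.5	c.450del	p.Ala150fs*64	rs759019641	.	LP	PVS1, PP5	9	62	.
AIM2	NM_004833.3	c.1029dup	p.*344Ileext*3	rs1557889335	0.0129792	LP	PM4, PM2, BP4	4	62	343
SNX16	NM_152836.3	c.1033T>C	p.*345Glnext*15	rs150053915	0.00199681	LP	PM4, PM2, BP4	4	62	344
CAMKK2	NM_001270486.1	c.1614dup	p.Gly539Argfs*3	.	.	VUS	PM2	8	62	556
PDE11A	NM_001077197.2	c.20_21del	p.Arg7Thrfs*30	rs202117698	0.00219649	VUS	PVS1, PP5, BS2	4	62	.
PCSK1	NM_000439.5	c.242G>A	p.Arg81Lys	.	.	VUS	PM2	4	62	.
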