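gene	label	sequence	fold	cell_line	mirna	end
MOR	uAUG1	gcccAUGcucc	1	HEK293	hsa-miR-146a	3p
MOR	uAUG1	gcccAUGcucc	1	HEK293	hsa-miR-202	3p
MOR	uAUG2	ggggAUGcuaa	2	HEK293	hsa-miR-324-5p	5p
MOR	uAUG2	ggggAUGcuaa	2	HEK293	hsa-miR-517b	5p
MOR	uAUG3	aaggAUGcgcc	3	HEK293	hsa-miR-323-5p	3p
MOR	uAUG3	aaggAUGcgcc	3	HEK293	hsa-miR-324-5p	5p
MOR	uAUG3	aaggAUGcgcc	3	HEK293	hsa-miR-450b-3p	3p
CHOP	uAUG1	uaucAUGuuaa	1	HeLa		
CHOP	uAUG2	aaagAUGagcg	6	HeLa	hsa-miR-574-3p	5p
CHOP	uAUG2	aaagAUGagcg	6	HeLa	hsa-miR-556-3p	3p
CHOP	uAUG3	gcagAUGugcu	2	HeLa	hsa-miR-219-2-3p	3p
MDM2	uAUG1	aaagAUGgagc	3	HeLa	hsa-miR-363	3p
MDM2	uAUG2	uggaAUGaucc	1	HeLa		
ADH5	uAUG1	gcccAUGccuc	4	HeLa	hsa-miR-146a	3p
ADH5	uAUG1	gcccAUGccuc	4	HeLa	hsa-miR-202	3p
ADH5	uAUG2	ccggAUGucag	4	HeLa	hsa-miR-219-1-3p	3p
ADH5	uAUG2	ccggAUGucag	4	HeLa	hsa-miR-219-2-3p	3p
ADH5	uAUG2	ccggAUGucag	4	HeLa	hsa-miR-487a	3p
ADH5	uAUG2	ccggAUGucag	4	HeLa	hsa-miR-489	5p
KLF13	uAUG1	cacaAUGcgcg	1	Jurkat	hsa-miR-323-5p	3p
KLF13	uAUG1	cacaAUGcgcg	1	Jurkat	hsa-miR-103	5p
KLF13	uAUG1	cacaAUGcgcg	1	Jurkat	hsa-miR-107	5p
KLF13	uAUG1	cacaAUGcgcg	1	Jurkat	hsa-miR-33a	5p
KLF13	uAUG2	ccccAUGcgcu	2	Jurkat	hsa-miR-586	5p
KLF13	uAUG2	ccccAUGcgcu	2	Jurkat	hsa-miR-202	3p
KLF13	uAUG3	gcggAUGcgcg	2	Jurkat	hsa-miR-450b-3p	3p
KLF13	uAUG3	gcggAUGcgcg	2	Jurkat	hsa-miR-324-5p	5p
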