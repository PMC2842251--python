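mirna	cell_line	expressed	source
hsa-miR-146a	HEK293	No	
hsa-miR-202	HEK293	No	
hsa-miR-324-5p	HEK293	Yes	ref42
hsa-miR-517b	HEK293	Yes	ref42
hsa-miR-323-5p	HEK293	No	
hsa-miR-450b-3p	HEK293	No	
hsa-miR-574-3p	HeLa	Yes	ref41
hsa-miR-574-3p	HeLa	Yes	ref42
hsa-miR-556-3p	HeLa	No	
hsa-miR-219-2-3p	HeLa	No	
hsa-miR-363	HeLa	Yes	ref42
hsa-miR-146a	HeLa	No	
hsa-miR-202	HeLa	No	
hsa-miR-219-1-3p	HeLa	No	
hsa-miR-487a	HeLa	No	
hsa-miR-489	HeLa	No	
hsa-miR-323-5p	Jurkat	No	
hsa-miR-103	Jurkat	Yes	ref41
hsa-miR-107	Jurkat	Yes	ref41
hsa-miR-33a	Jurkat	Yes	ref44
hsa-miR-33a	Jurkat	Yes	ref45
hsa-miR-586	Jurkat	No	
hsa-miR-202	Jurkat	No	
hsa-miR-450b-3p	Jurkat	No	
hsa-miR-324-5p	Jurkat	Yes	ref41
hsa-miR-324-5p	Jurkat	Yes	ref44
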