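source	target	layer	evidence
SP1	miR-200c-3p	gene-miRNA	lit
SP1	CYP1B1-AS1	gene-lncRNA	lit
miR-200c-3p	CYP1B1-AS1	miRNA-lncRNA	lit
EP300	miR-150-5p	gene-miRNA	lit
EP300	ZFAS1	gene-lncRNA	lit
miR-150-5p	ZFAS1	miRNA-lncRNA	lit
SMAD4	miR-185-5p	gene-miRNA	lit
SMAD4	ZFAS1	gene-lncRNA	lit
miR-185-5p	ZFAS1	miRNA-lncRNA	lit
CEBPA	miR-125b-5p	gene-miRNA	lit
ESRRA	miR-125b-5p	gene-miRNA	lit
EP300	miR-574-3p	gene-miRNA	lit
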