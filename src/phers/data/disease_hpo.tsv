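disease_id	hpo_term_id	gene	inheritance	provisional
OMIM:143100	HP:0000716	HTT	autosomal dominant	false
OMIM:143100	HP:0001249	HTT	autosomal dominant	false
OMIM:143100	HP:0002072	HTT	autosomal dominant	false
OMIM:166200	HP:0000924	COL1A1	autosomal dominant	false
OMIM:166200	HP:0000938	COL1A1	autosomal dominant	false
OMIM:166200	HP:0002659	COL1A1	autosomal dominant	false
OMIM:166200	HP:0002758	COL1A1	autosomal dominant	false
OMIM:174600	HP:0002037	APC	autosomal dominant	false
OMIM:174600	HP:0005263	APC	autosomal dominant	false
OMIM:174600	HP:0100273	APC	autosomal dominant	false
OMIM:219700	HP:0000952	CFTR	autosomal recessive	false
OMIM:219700	HP:0001738	CFTR	autosomal recessive	false
OMIM:219700	HP:0002110	CFTR	autosomal recessive	false
OMIM:219700	HP:0002205	CFTR	autosomal recessive	false
OMIM:219700	HP:0006528	CFTR	autosomal recessive	false
OMIM:219700	HP:0011108	CFTR	autosomal recessive	true
OMIM:613490	HP:0001392	SERPINA1	autosomal recessive	false
OMIM:613490	HP:0002110	SERPINA1	autosomal recessive	false
OMIM:613490	HP:0006536	SERPINA1	autosomal recessive	false
OMIM:999901	HP:0001909	KRAS	somatic	false
OMIM:999901	HP:0002664	KRAS	somatic	false
OMIM:999901	HP:0004377	KRAS	somatic	false
OMIM:999902	HP:0001627	MYH7	autosomal recessive	false
OMIM:999902	HP:0011675	MYH7	autosomal recessive	false
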