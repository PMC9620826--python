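disease_id	icd	flag
OMIM:143100	333.4	9
OMIM:143100	G10	10
OMIM:219700	277.00	9
OMIM:219700	277.02	9
OMIM:219700	E84.0	10
OMIM:219700	E84.9	10
OMIM:613490	273.4	9
OMIM:613490	E88.01	10
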