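disease_id	phecode
OMIM:143100	296.2
OMIM:143100	317
OMIM:143100	331
OMIM:166200	715
OMIM:166200	735
OMIM:166200	743.1
OMIM:166200	759
OMIM:174600	153
OMIM:174600	535
OMIM:174600	555
OMIM:219700	480
OMIM:219700	496
OMIM:219700	502
OMIM:219700	577
OMIM:613490	496
OMIM:613490	502
OMIM:613490	571.5
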