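icd	flag	phecode
486	9	480
J18.9	10	480
496	9	496
J44.9	10	496
J44.0	10	496
J44.0	10	480
494	9	502
J47.9	10	502
577.0	9	577
K86.9	10	577
571.5	9	571.5
K74.60	10	571.5
153.9	9	153
C18.9	10	153
555.9	9	555
K50.90	10	555
535.50	9	535
K29.70	10	535
331.9	9	331
G31.9	10	331
311	9	296.2
F32.9	10	296.2
317	9	317
F79	10	317
736.9	9	735
M21.90	10	735
733.00	9	743.1
M81.0	10	743.1
716.90	9	715
M12.9	10	715
759.9	9	759
Q89.9	10	759
401.9	9	401.1
I10	10	401.1
250.00	9	250.2
E11.9	10	250.2
272.4	9	272.1
E78.5	10	272.1
427.31	9	427.2
I48.91	10	427.2
428.0	9	428
I50.9	10	428
530.81	9	530.1
K21.9	10	530.1
585.9	9	585
N18.9	10	585
599.0	9	599
N39.0	10	599
280.9	9	280.1
D50.9	10	280.1
327.23	9	327.3
G47.33	10	327.3
715.90	9	740
M19.90	10	740
008.8	9	008
A09	10	008
277.00	9	499
277.02	9	499
E84.0	10	499
E84.9	10	499
273.4	9	270.3
E88.01	10	270.3
333.4	9	333
G10	10	333
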