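hpo_term_id	phecode	match_quality
HP:0000716	296.2	broader
HP:0000924	759	broader
HP:0000938	743.1	exact
HP:0001249	317	exact
HP:0001392	571.5	broader
HP:0001627	428	broader
HP:0001738	577	broader
HP:0001909	280.1	broader
HP:0002037	555	exact
HP:0002072	331	broader
HP:0002110	502	exact
HP:0002205	480	broader
HP:0002659	735	broader
HP:0002664	153	broader
HP:0002758	715	broader
HP:0004377	008	broader
HP:0005263	535	broader
HP:0006528	496	exact
HP:0006536	496	broader
HP:0011108	008	broader
HP:0011675	427.2	broader
HP:0100273	153	broader
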