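taxon_id	2018-01	2018-02	2018-03	2018-04
taxon_a	10	10	0	2
taxon_b	10	0	4	2
taxon_c	0	5	6	2
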