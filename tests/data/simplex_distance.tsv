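sample_id	s0	s1	s2	s3
s0	0.0	1.0	1.0	1.0
s1	1.0	0.0	1.0	1.0
s2	1.0	1.0	0.0	1.0
s3	1.0	1.0	1.0	0.0
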