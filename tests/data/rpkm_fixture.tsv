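gene	gene_length	s0	s1	s2	s3	s4	s5	s6	s7
gA	1000	10	10	10	10	10	10	10	10
gB	1000	0	0	0	0	0	0	0	0
gC	1000	2	2	2	2	2	2	2	2
gD	1000	3	0	0	0	0	0	0	0
gE	1000	0	0	0	3	0	0	0	0
gF	1000	999985	999988	999988	999985	999988	999988	999988	999988
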