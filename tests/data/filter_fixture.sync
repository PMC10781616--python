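chr1	1	A	40:0:0:20:0:0	35:0:0:25:0:0
chr1	2	A	40:0:0:20:0:0	35:0:0:25:0:0
chr1	3	A	40:0:0:20:0:0	35:0:0:25:0:0
chr1	4	A	20:0:0:4:0:0	35:0:0:25:0:0
chr1	5	A	40:0:0:20:0:0	35:0:0:25:0:0
chr1	6	A	40:0:0:20:0:0	35:0:0:25:0:0
chr1	7	A	40:0:0:20:0:0	35:0:0:25:0:0
chr1	8	A	57:0:0:3:0:0	58:0:0:2:0:0
chr1	9	A	40:0:0:20:0:0	35:0:0:25:0:0
chr1	10	A	40:0:0:20:0:0	35:0:0:25:0:0
chr1	11	A	40:0:0:20:0:0	35:0:0:25:0:0
chr1	12	A	180:0:0:30:0:0	35:0:0:25:0:0
chr1	13	A	40:0:0:20:0:0	35:0:0:25:0:0
chr1	14	A	40:0:0:20:0:0	35:0:0:25:0:0
chr1	15	A	40:0:0:20:0:0	35:0:0:25:0:0
chr1	16	A	40:0:0:20:0:0	35:0:0:25:0:0
chr1	17	A	40:0:0:20:0:0	35:0:0:25:0:0
chr1	18	A	40:0:0:20:0:0	35:0:0:25:0:0
chr1	19	A	40:0:0:20:0:0	35:0:0:25:0:0
chr1	20	A	40:0:0:20:0:0	35:0:0:25:0:0
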