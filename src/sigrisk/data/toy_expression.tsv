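gene	p1	p2	p3	p4	p5	p6
GENE1	7.1	6.8	8.2	7.9	6.5	7.4
GENE2	5.2	5.9	4.8	5.5	6.1	5.0
GENE3	9.0	8.7	9.4	8.9	9.2	8.6
GENE4	6.6	7.2	6.9	7.0	6.4	7.3
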