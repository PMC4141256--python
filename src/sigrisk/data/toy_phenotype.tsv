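sample	time	event	age	er_status
p1	12.5	1	61	+
p2	40.0	0	55	-
p3	8.2	1	67	+
p4	25.0	1	49	-
p5	60.0	0	72	+
p6	33.1	0	58	-
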