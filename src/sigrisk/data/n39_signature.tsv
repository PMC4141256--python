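symbol	kd_direction	support
ADK	0	
AP2B1	0	
AVL9	0	
CANX	0	
DBT	0	
DHRS7	0	
DONSON	0	
FAM190B	0	
FGFR1	0	
FOXN3	0	
FZD5	0	
GGH	0	
GM2A	0	
IGFBP5	0	
ITSN2	0	
LAMC1	0	
LIFR	0	
METTL7A	0	
MT1F	0	
MT1G	0	
MT1P2	0	
MT1X	0	
MT2A	0	
NAB1	0	
NCOA1	0	
NCOR1	0	
PAPOLA	0	
PPME1	0	
PPP1R13L	0	
PRKAR2A	0	
RABEP1	0	
RBBP8	0	
SGPL1	0	
SIRT1	0	
SNX2	0	
SREK1	0	
TAF1B	0	
TMED5	0	
ZMIZ2	0	
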