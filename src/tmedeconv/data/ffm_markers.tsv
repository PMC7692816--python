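set_name	gene
FFM1	DCN
FFM1	LUM
FFM1	FBLN1
FFM1	PDGFRA
FFM1	ACTA2
FFM1	THY1
FFM2	COL1A1
FFM2	COL1A2
FFM2	COL3A1
FFM2	COL5A1
FFM2	COL5A2
FFM3	COL4A1
FFM3	COL4A2
FFM3	COL4A3
FFM3	COL4A5
FFM4	COL6A1
FFM4	COL6A2
FFM4	COL6A3
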