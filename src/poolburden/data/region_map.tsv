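gene	region
GP6	GP6
ITGA2	ITGA2
ITGA2B	ITGA2B/ITGB3
ITGB3	ITGA2B/ITGB3
ITPR1	ITPR1
P2RY1	P2RY1/P2RY12
P2RY12	P2RY1/P2RY12
P2RY2	P2RY2
PEAR1	PEAR1
PTAFR	PTAFR
SELP	SELP
PTGIR	PTGIR
GP1BA	.
RAF1	.
FERMT3	.
GP9	.
GP5	.
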