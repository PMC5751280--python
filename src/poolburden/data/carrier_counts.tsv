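region	carriers_ctrl	carriers_case	carriers_ctrl_subset	carriers_case_subset
GP6	3	1	0	0
ITGA2	0	2	0	2
ITGA2B/ITGB3	2	7	2	5
ITPR1	2	3	1	2
P2RY1/P2RY12	1	10	1	10
P2RY2	2	3	1	3
PEAR1	0	1	0	0
PTAFR	0	1	0	1
SELP	0	2	0	2
PTGIR	0	2	0	2
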