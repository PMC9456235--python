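No.	E116:HA	R119:Ak	I136:Ak	P137:Ak	L160:Ak	L172:Ak	Y211:PO	L214:HA	L214:Ak	E215:HD	A218:Ak
59	0	0	1	1	1	0	0	0	1	0	1
68	0	0	1	1	1	0	0	0	1	0	1
81	0	0	1	1	1	0	0	0	1	1	1
58	0	0	1	1	1	0	0	0	1	0	1
65	0	0	1	1	0	0	0	0	1	0	1
89	0	0	1	1	1	1	0	1	1	0	1
49	0	0	1	1	1	0	0	0	1	0	1
57	0	1	1	1	0	0	1	0	1	0	0
77	1	0	1	1	0	0	1	0	1	0	0
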