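No.	F36:PO	L47:Ak	S76:HD	S79:HD	P87:HA	P87:Ak	V88:Ak	H89:HD	H89:PO	M107:Ak	L110:Ak
51	1	0	0	1	1	0	1	0	1	1	0
19	1	1	0	0	0	0	1	1	0	1	0
31	1	0	0	0	0	0	1	0	1	1	1
14	1	1	0	0	0	1	1	0	1	1	0
39	1	0	0	1	0	0	1	0	1	1	0
40	1	0	0	1	0	0	1	0	1	1	0
42	1	1	1	0	0	1	1	0	1	1	0
27	1	0	0	1	0	0	1	0	1	1	1
32	1	0	0	0	0	0	1	0	1	1	1
1	1	1	0	0	0	1	1	0	1	1	0
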