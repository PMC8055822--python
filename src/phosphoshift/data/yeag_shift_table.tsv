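protein	site	wt_shift	ko_shift	delta
GlyA	Y55	-3.39	7.58	10.97
AceB	T467	-0.60	5.01	5.61
SerA	S61	-0.42	4.11	4.53
Mdh	T211	-0.34	3.66	4.00
AceA	T5	0.21	3.91	3.70
PykA	S350	-0.55	3.01	3.57
CysK	S133	0.26	3.71	3.45
KdsA	S65	0.10	3.30	3.20
KdsA	S64	0.10	3.10	2.99
TpiA	T179	0.42	3.31	2.89
GpmA	Y92	0.00	2.78	2.78
Pnp	S652	-0.68	2.08	2.76
Pgk	S86	-0.77	1.95	2.72
RpoA	T22	0.54	2.69	2.15
TpiA	S177	0.48	2.53	2.04
FusA	S692	0.50	2.03	1.53
PurM	S191	-0.26	1.26	1.52
FbaA	S268	0.57	1.91	1.34
FolE	S136	-0.41	0.83	1.23
Fbp	S264	1.53	2.69	1.17
InfB	T713	0.13	0.81	0.69
YgaU	S108	1.21	1.88	0.66
OmpF	Y44	0.79	1.44	0.65
CysK	S289	1.55	2.18	0.63
MglA	S406	-2.36	-1.76	0.60
Pgi	T26	-0.66	-0.20	0.46
DnaK	T417	1.58	1.83	0.25
GatY	T233	2.42	2.67	0.24
Pgm	S146	0.11	0.27	0.16
RsxG	T174	-0.12	-0.09	0.03
Hfq	T49	1.45	1.48	0.03
GlnA	Y398	-0.39	-0.65	-0.26
PpsA	T413	1.82	1.13	-0.69
OmpT	S284	0.76	0.02	-0.75
Tsf	S7	1.99	0.85	-1.15
YjhQ	T11	-0.31	-2.14	-1.83
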