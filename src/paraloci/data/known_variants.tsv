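gene	g_position	ref	alt	rs_id
CYP2D50-1	2605	C	A	rs1148503187
CYP2D50-1	4192	C	A	rs1137288236
CYP2D50-1	4240	T	G	rs396861920
CYP2D50-1	4255	T	A	rs394932323
CYP2D82	83	G	A	rs1141439398
CYP2D82	85	C	T	rs1150936359
CYP2D82	1984	G	C	rs1143153764
CYP2D82	2214	T	G	rs1138659802
CYP2D82	2635	A	G	rs1147081710
CYP2D82	2673	A	G	rs1145722969
CYP2D82	2674	A	G	rs1143545655
CYP2D82	2691	C	G	rs394128659
CYP2D82	2733	A	G	rs1136055998
CYP2D82	2767	T	A	rs1142815816
CYP2D82	3403	T	C	rs396631299
CYP2D82	3469	T	G	rs1148651933
CYP2D82	3472	A	G	rs1136958956
CYP2D82	3493	A	G	rs395645145
CYP2D82	4104	C	T	rs1148309512
CYP2D82	4141	G	A	rs1145664752
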