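residue	atom	radius	charge	epsilon	rmin_half
*	C	1.70	0.0	0.070	2.00
*	N	1.55	0.0	0.170	1.85
*	O	1.52	0.0	0.120	1.70
*	S	1.80	0.0	0.450	2.00
*	H	1.20	0.0	0.030	0.50
*	P	1.80	0.0	0.585	2.15
LYS	NZ	1.55	1.0	0.170	1.85
ARG	NH1	1.55	0.5	0.170	1.85
ARG	NH2	1.55	0.5	0.170	1.85
ASP	OD1	1.52	-0.5	0.120	1.70
ASP	OD2	1.52	-0.5	0.120	1.70
GLU	OE1	1.52	-0.5	0.120	1.70
GLU	OE2	1.52	-0.5	0.120	1.70
HIS	ND1	1.55	0.0	0.170	1.85
HIS	NE2	1.55	0.0	0.170	1.85
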