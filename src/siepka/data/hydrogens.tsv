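label	hname	parent	ref2	ref3	length	angle	torsion	kind
*	H	N	-	-	1.01	119.0	0.0	bisect
SER	HG	OG	CB	CA	0.96	108.5	180.0	rot
THR	HG1	OG1	CB	CA	0.96	108.5	180.0	rot
CYS	HG	SG	CB	CA	1.34	96.0	180.0	rot
TYR	HH	OH	CZ	CE1	0.96	110.0	0.0	rot
TRP	HE1	NE1	-	-	1.01	125.0	0.0	bisect
ASN	HD21	ND2	CG	OD1	1.01	120.0	180.0	torsion
ASN	HD22	ND2	CG	OD1	1.01	120.0	0.0	torsion
GLN	HE21	NE2	CD	OE1	1.01	120.0	180.0	torsion
GLN	HE22	NE2	CD	OE1	1.01	120.0	0.0	torsion
LYS	HZ1	NZ	CE	CD	1.01	109.5	60.0	rot3
LYS	HZ2	NZ	CE	CD	1.01	109.5	180.0	rot3
LYS	HZ3	NZ	CE	CD	1.01	109.5	300.0	rot3
ARG	HE	NE	-	-	1.01	120.0	0.0	bisect
ARG	HH11	NH1	CZ	NE	1.01	120.0	0.0	torsion
ARG	HH12	NH1	CZ	NE	1.01	120.0	180.0	torsion
ARG	HH21	NH2	CZ	NE	1.01	120.0	0.0	torsion
ARG	HH22	NH2	CZ	NE	1.01	120.0	180.0	torsion
HID	HD1	ND1	-	-	1.01	125.0	0.0	bisect
HIE	HE2	NE2	-	-	1.01	125.0	0.0	bisect
HIP	HD1	ND1	-	-	1.01	125.0	0.0	bisect
HIP	HE2	NE2	-	-	1.01	125.0	0.0	bisect
ASH	HD2	OD2	CG	OD1	0.96	113.0	0.0	torsion
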