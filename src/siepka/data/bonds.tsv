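label	atom1	atom2
ALA	N	H
ALA	N	CA
ALA	CA	C
ALA	C	O
ALA	CA	CB
GLY	N	H
GLY	N	CA
GLY	CA	C
GLY	C	O
SER	N	H
SER	N	CA
SER	CA	C
SER	C	O
SER	CA	CB
SER	CB	OG
SER	OG	HG
THR	N	H
THR	N	CA
THR	CA	C
THR	C	O
THR	CA	CB
THR	CB	OG1
THR	OG1	HG1
THR	CB	CG2
CYS	N	H
CYS	N	CA
CYS	CA	C
CYS	C	O
CYS	CA	CB
CYS	CB	SG
CYS	SG	HG
VAL	N	H
VAL	N	CA
VAL	CA	C
VAL	C	O
VAL	CA	CB
VAL	CB	CG1
VAL	CB	CG2
LEU	N	H
LEU	N	CA
LEU	CA	C
LEU	C	O
LEU	CA	CB
LEU	CB	CG
LEU	CG	CD1
LEU	CG	CD2
ILE	N	H
ILE	N	CA
ILE	CA	C
ILE	C	O
ILE	CA	CB
ILE	CB	CG1
ILE	CB	CG2
ILE	CG1	CD1
MET	N	H
MET	N	CA
MET	CA	C
MET	C	O
MET	CA	CB
MET	CB	CG
MET	CG	SD
MET	SD	CE
PRO	N	CA
PRO	CA	C
PRO	C	O
PRO	CA	CB
PRO	CB	CG
PRO	CG	CD
PRO	CD	N
PHE	N	H
PHE	N	CA
PHE	CA	C
PHE	C	O
PHE	CA	CB
PHE	CB	CG
PHE	CG	CD1
PHE	CG	CD2
PHE	CD1	CE1
PHE	CD2	CE2
PHE	CE1	CZ
PHE	CE2	CZ
TYR	N	H
TYR	N	CA
TYR	CA	C
TYR	C	O
TYR	CA	CB
TYR	CB	CG
TYR	CG	CD1
TYR	CG	CD2
TYR	CD1	CE1
TYR	CD2	CE2
TYR	CE1	CZ
TYR	CE2	CZ
TYR	CZ	OH
TYR	OH	HH
TRP	N	H
TRP	N	CA
TRP	CA	C
TRP	C	O
TRP	CA	CB
TRP	CB	CG
TRP	CG	CD1
TRP	CG	CD2
TRP	CD1	NE1
TRP	NE1	HE1
TRP	NE1	CE2
TRP	CE2	CD2
TRP	CD2	CE3
TRP	CE2	CZ2
TRP	CE3	CZ3
TRP	CZ2	CH2
TRP	CZ3	CH2
ASN	N	H
ASN	N	CA
ASN	CA	C
ASN	C	O
ASN	CA	CB
ASN	CB	CG
ASN	CG	OD1
ASN	CG	ND2
ASN	ND2	HD21
ASN	ND2	HD22
GLN	N	H
GLN	N	CA
GLN	CA	C
GLN	C	O
GLN	CA	CB
GLN	CB	CG
GLN	CG	CD
GLN	CD	OE1
GLN	CD	NE2
GLN	NE2	HE21
GLN	NE2	HE22
ASP	N	H
ASP	N	CA
ASP	CA	C
ASP	C	O
ASP	CA	CB
ASP	CB	CG
ASP	CG	OD1
ASP	CG	OD2
ASH	N	H
ASH	N	CA
ASH	CA	C
ASH	C	O
ASH	CA	CB
ASH	CB	CG
ASH	CG	OD1
ASH	CG	OD2
ASH	OD2	HD2
GLU	N	H
GLU	N	CA
GLU	CA	C
GLU	C	O
GLU	CA	CB
GLU	CB	CG
GLU	CG	CD
GLU	CD	OE1
GLU	CD	OE2
LYS	N	H
LYS	N	CA
LYS	CA	C
LYS	C	O
LYS	CA	CB
LYS	CB	CG
LYS	CG	CD
LYS	CD	CE
LYS	CE	NZ
LYS	NZ	HZ1
LYS	NZ	HZ2
LYS	NZ	HZ3
ARG	N	H
ARG	N	CA
ARG	CA	C
ARG	C	O
ARG	CA	CB
ARG	CB	CG
ARG	CG	CD
ARG	CD	NE
ARG	NE	HE
ARG	NE	CZ
ARG	CZ	NH1
ARG	CZ	NH2
ARG	NH1	HH11
ARG	NH1	HH12
ARG	NH2	HH21
ARG	NH2	HH22
HID	N	H
HID	N	CA
HID	CA	C
HID	C	O
HID	CA	CB
HID	CB	CG
HID	CG	ND1
HID	CG	CD2
HID	ND1	CE1
HID	ND1	HD1
HID	CE1	NE2
HID	NE2	CD2
HIE	N	H
HIE	N	CA
HIE	CA	C
HIE	C	O
HIE	CA	CB
HIE	CB	CG
HIE	CG	ND1
HIE	CG	CD2
HIE	ND1	CE1
HIE	CE1	NE2
HIE	NE2	HE2
HIE	NE2	CD2
HIP	N	H
HIP	N	CA
HIP	CA	C
HIP	C	O
HIP	CA	CB
HIP	CB	CG
HIP	CG	ND1
HIP	CG	CD2
HIP	ND1	CE1
HIP	ND1	HD1
HIP	CE1	NE2
HIP	NE2	HE2
HIP	NE2	CD2
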