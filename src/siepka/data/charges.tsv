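label	atom	element	charge	radius
ALA	N	N	-0.4157	1.8240
ALA	H	H	0.2719	0.6000
ALA	CA	C	0.1160	1.9080
ALA	C	C	0.5973	1.9080
ALA	O	O	-0.5679	1.6612
ALA	CB	C	-0.0016	1.9080
GLY	N	N	-0.4157	1.8240
GLY	H	H	0.2719	0.6000
GLY	CA	C	0.1144	1.9080
GLY	C	C	0.5973	1.9080
GLY	O	O	-0.5679	1.6612
SER	N	N	-0.4157	1.8240
SER	H	H	0.2719	0.6000
SER	CA	C	0.1160	1.9080
SER	C	C	0.5973	1.9080
SER	O	O	-0.5679	1.6612
SER	CB	C	0.2255	1.9080
SER	OG	O	-0.6546	1.6612
SER	HG	H	0.4275	0.6000
THR	N	N	-0.4157	1.8240
THR	H	H	0.2719	0.6000
THR	CA	C	0.1160	1.9080
THR	C	C	0.5973	1.9080
THR	O	O	-0.5679	1.6612
THR	CB	C	0.2643	1.9080
THR	OG1	O	-0.6761	1.6612
THR	HG1	H	0.4102	0.6000
THR	CG2	C	0.0000	1.9080
CYS	N	N	-0.4157	1.8240
CYS	H	H	0.2719	0.6000
CYS	CA	C	0.1160	1.9080
CYS	C	C	0.5973	1.9080
CYS	O	O	-0.5679	1.6612
CYS	CB	C	0.1170	1.9080
CYS	SG	S	-0.3119	2.0000
CYS	HG	H	0.1933	0.6000
VAL	N	N	-0.4157	1.8240
VAL	H	H	0.2719	0.6000
VAL	CA	C	0.1160	1.9080
VAL	C	C	0.5973	1.9080
VAL	O	O	-0.5679	1.6612
VAL	CB	C	-0.0016	1.9080
VAL	CG1	C	0.0000	1.9080
VAL	CG2	C	0.0000	1.9080
LEU	N	N	-0.4157	1.8240
LEU	H	H	0.2719	0.6000
LEU	CA	C	0.1160	1.9080
LEU	C	C	0.5973	1.9080
LEU	O	O	-0.5679	1.6612
LEU	CB	C	-0.1016	1.9080
LEU	CG	C	0.1000	1.9080
LEU	CD1	C	0.0000	1.9080
LEU	CD2	C	0.0000	1.9080
ILE	N	N	-0.4157	1.8240
ILE	H	H	0.2719	0.6000
ILE	CA	C	0.1160	1.9080
ILE	C	C	0.5973	1.9080
ILE	O	O	-0.5679	1.6612
ILE	CB	C	-0.0016	1.9080
ILE	CG1	C	0.0000	1.9080
ILE	CG2	C	0.0000	1.9080
ILE	CD1	C	0.0000	1.9080
MET	N	N	-0.4157	1.8240
MET	H	H	0.2719	0.6000
MET	CA	C	0.1160	1.9080
MET	C	C	0.5973	1.9080
MET	O	O	-0.5679	1.6612
MET	CB	C	0.0621	1.9080
MET	CG	C	0.0600	1.9080
MET	SD	S	-0.2737	2.0000
MET	CE	C	0.1500	1.9080
PRO	N	N	-0.2548	1.8240
PRO	CA	C	0.1160	1.9080
PRO	C	C	0.5973	1.9080
PRO	O	O	-0.5679	1.6612
PRO	CB	C	0.0000	1.9080
PRO	CG	C	0.0000	1.9080
PRO	CD	C	0.1094	1.9080
PHE	N	N	-0.4157	1.8240
PHE	H	H	0.2719	0.6000
PHE	CA	C	0.1160	1.9080
PHE	C	C	0.5973	1.9080
PHE	O	O	-0.5679	1.6612
PHE	CB	C	-0.0016	1.9080
PHE	CG	C	0.0000	1.9080
PHE	CD1	C	0.0000	1.9080
PHE	CD2	C	0.0000	1.9080
PHE	CE1	C	0.0000	1.9080
PHE	CE2	C	0.0000	1.9080
PHE	CZ	C	0.0000	1.9080
TYR	N	N	-0.4157	1.8240
TYR	H	H	0.2719	0.6000
TYR	CA	C	0.1160	1.9080
TYR	C	C	0.5973	1.9080
TYR	O	O	-0.5679	1.6612
TYR	CB	C	-0.1655	1.9080
TYR	CG	C	0.0000	1.9080
TYR	CD1	C	0.0000	1.9080
TYR	CD2	C	0.0000	1.9080
TYR	CE1	C	0.0000	1.9080
TYR	CE2	C	0.0000	1.9080
TYR	CZ	C	0.3226	1.9080
TYR	OH	O	-0.5579	1.6612
TYR	HH	H	0.3992	0.6000
TRP	N	N	-0.4157	1.8240
TRP	H	H	0.2719	0.6000
TRP	CA	C	0.1160	1.9080
TRP	C	C	0.5973	1.9080
TRP	O	O	-0.5679	1.6612
TRP	CB	C	-0.1390	1.9080
TRP	CG	C	-0.1000	1.9080
TRP	CD1	C	0.1000	1.9080
TRP	NE1	N	-0.3418	1.8240
TRP	HE1	H	0.3412	0.6000
TRP	CE2	C	0.1380	1.9080
TRP	CD2	C	0.0000	1.9080
TRP	CE3	C	0.0000	1.9080
TRP	CZ2	C	0.0000	1.9080
TRP	CZ3	C	0.0000	1.9080
TRP	CH2	C	0.0000	1.9080
ASN	N	N	-0.4157	1.8240
ASN	H	H	0.2719	0.6000
ASN	CA	C	0.1160	1.9080
ASN	C	C	0.5973	1.9080
ASN	O	O	-0.5679	1.6612
ASN	CB	C	0.0881	1.9080
ASN	CG	C	0.5833	1.9080
ASN	OD1	O	-0.5931	1.6612
ASN	ND2	N	-0.9191	1.8240
ASN	HD21	H	0.4196	0.6000
ASN	HD22	H	0.4196	0.6000
GLN	N	N	-0.4157	1.8240
GLN	H	H	0.2719	0.6000
GLN	CA	C	0.1160	1.9080
GLN	C	C	0.5973	1.9080
GLN	O	O	-0.5679	1.6612
GLN	CB	C	0.0881	1.9080
GLN	CG	C	0.0000	1.9080
GLN	CD	C	0.5833	1.9080
GLN	OE1	O	-0.5931	1.6612
GLN	NE2	N	-0.9191	1.8240
GLN	HE21	H	0.4196	0.6000
GLN	HE22	H	0.4196	0.6000
ASP	N	N	-0.4157	1.8240
ASP	H	H	0.2719	0.6000
ASP	CA	C	0.1160	1.9080
ASP	C	C	0.5973	1.9080
ASP	O	O	-0.5679	1.6612
ASP	CB	C	-0.1982	1.9080
ASP	CG	C	0.7994	1.9080
ASP	OD1	O	-0.8014	1.6612
ASP	OD2	O	-0.8014	1.6612
ASH	N	N	-0.4157	1.8240
ASH	H	H	0.2719	0.6000
ASH	CA	C	0.1160	1.9080
ASH	C	C	0.5973	1.9080
ASH	O	O	-0.5679	1.6612
ASH	CB	C	0.0705	1.9080
ASH	CG	C	0.6462	1.9080
ASH	OD1	O	-0.5554	1.6612
ASH	OD2	O	-0.6376	1.6612
ASH	HD2	H	0.4747	0.6000
GLU	N	N	-0.4157	1.8240
GLU	H	H	0.2719	0.6000
GLU	CA	C	0.1160	1.9080
GLU	C	C	0.5973	1.9080
GLU	O	O	-0.5679	1.6612
GLU	CB	C	0.0306	1.9080
GLU	CG	C	-0.2000	1.9080
GLU	CD	C	0.8054	1.9080
GLU	OE1	O	-0.8188	1.6612
GLU	OE2	O	-0.8188	1.6612
LYS	N	N	-0.4157	1.8240
LYS	H	H	0.2719	0.6000
LYS	CA	C	0.1160	1.9080
LYS	C	C	0.5973	1.9080
LYS	O	O	-0.5679	1.6612
LYS	CB	C	0.0378	1.9080
LYS	CG	C	0.0000	1.9080
LYS	CD	C	0.0000	1.9080
LYS	CE	C	0.3260	1.9080
LYS	NZ	N	-0.3854	1.8240
LYS	HZ1	H	0.3400	0.6000
LYS	HZ2	H	0.3400	0.6000
LYS	HZ3	H	0.3400	0.6000
ARG	N	N	-0.4157	1.8240
ARG	H	H	0.2719	0.6000
ARG	CA	C	0.1160	1.9080
ARG	C	C	0.5973	1.9080
ARG	O	O	-0.5679	1.6612
ARG	CB	C	-0.0165	1.9080
ARG	CG	C	0.0000	1.9080
ARG	CD	C	0.2000	1.9080
ARG	NE	N	-0.5295	1.8240
ARG	HE	H	0.3456	0.6000
ARG	CZ	C	0.8076	1.9080
ARG	NH1	N	-0.8000	1.8240
ARG	HH11	H	0.4478	0.6000
ARG	HH12	H	0.4478	0.6000
ARG	NH2	N	-0.8000	1.8240
ARG	HH21	H	0.4478	0.6000
ARG	HH22	H	0.4478	0.6000
HID	N	N	-0.4157	1.8240
HID	H	H	0.2719	0.6000
HID	CA	C	0.1160	1.9080
HID	C	C	0.5973	1.9080
HID	O	O	-0.5679	1.6612
HID	CB	C	0.0251	1.9080
HID	CG	C	-0.0266	1.9080
HID	ND1	N	-0.3811	1.8240
HID	HD1	H	0.3649	0.6000
HID	CE1	C	0.3449	1.9080
HID	NE2	N	-0.5727	1.8240
HID	CD2	C	0.2439	1.9080
HIE	N	N	-0.4157	1.8240
HIE	H	H	0.2719	0.6000
HIE	CA	C	0.1160	1.9080
HIE	C	C	0.5973	1.9080
HIE	O	O	-0.5679	1.6612
HIE	CB	C	0.0279	1.9080
HIE	CG	C	0.1868	1.9080
HIE	ND1	N	-0.5432	1.8240
HIE	CE1	C	0.3070	1.9080
HIE	NE2	N	-0.2795	1.8240
HIE	HE2	H	0.3339	0.6000
HIE	CD2	C	-0.0345	1.9080
HIP	N	N	-0.4157	1.8240
HIP	H	H	0.2719	0.6000
HIP	CA	C	0.1160	1.9080
HIP	C	C	0.5973	1.9080
HIP	O	O	-0.5679	1.6612
HIP	CB	C	0.1765	1.9080
HIP	CG	C	-0.0014	1.9080
HIP	ND1	N	-0.1513	1.8240
HIP	HD1	H	0.3866	0.6000
HIP	CE1	C	0.2511	1.9080
HIP	NE2	N	-0.1718	1.8240
HIP	HE2	H	0.3911	0.6000
HIP	CD2	C	0.1176	1.9080
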