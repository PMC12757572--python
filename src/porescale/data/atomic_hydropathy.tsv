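# Binarized atomic hydropathy: -0.5 kcal hydrophobic, +0.5 kcal hydrophilic.
# Polar atoms: N/O everywhere; Cys SG; amide/carboxyl/guanidinium carbons,
# backbone carbonyl C, His CE1; hydrogens bound to N/O/S. All else apolar.
residue_name	atom_name	weight
GLY	N	+0.5
GLY	CA	-0.5
GLY	C	+0.5
GLY	O	+0.5
GLY	OXT	+0.5
GLY	H	+0.5
GLY	H1	+0.5
GLY	H2	+0.5
GLY	H3	+0.5
GLY	HN	+0.5
GLY	HXT	+0.5
ALA	N	+0.5
ALA	CA	-0.5
ALA	C	+0.5
ALA	O	+0.5
ALA	CB	-0.5
ALA	OXT	+0.5
ALA	H	+0.5
ALA	H1	+0.5
ALA	H2	+0.5
ALA	H3	+0.5
ALA	HN	+0.5
ALA	HXT	+0.5
VAL	N	+0.5
VAL	CA	-0.5
VAL	C	+0.5
VAL	O	+0.5
VAL	CB	-0.5
VAL	CG1	-0.5
VAL	CG2	-0.5
VAL	OXT	+0.5
VAL	H	+0.5
VAL	H1	+0.5
VAL	H2	+0.5
VAL	H3	+0.5
VAL	HN	+0.5
VAL	HXT	+0.5
LEU	N	+0.5
LEU	CA	-0.5
LEU	C	+0.5
LEU	O	+0.5
LEU	CB	-0.5
LEU	CG	-0.5
LEU	CD1	-0.5
LEU	CD2	-0.5
LEU	OXT	+0.5
LEU	H	+0.5
LEU	H1	+0.5
LEU	H2	+0.5
LEU	H3	+0.5
LEU	HN	+0.5
LEU	HXT	+0.5
ILE	N	+0.5
ILE	CA	-0.5
ILE	C	+0.5
ILE	O	+0.5
ILE	CB	-0.5
ILE	CG1	-0.5
ILE	CG2	-0.5
ILE	CD1	-0.5
ILE	OXT	+0.5
ILE	H	+0.5
ILE	H1	+0.5
ILE	H2	+0.5
ILE	H3	+0.5
ILE	HN	+0.5
ILE	HXT	+0.5
PRO	N	+0.5
PRO	CA	-0.5
PRO	C	+0.5
PRO	O	+0.5
PRO	CB	-0.5
PRO	CG	-0.5
PRO	CD	-0.5
PRO	OXT	+0.5
PRO	H	+0.5
PRO	H1	+0.5
PRO	H2	+0.5
PRO	H3	+0.5
PRO	HN	+0.5
PRO	HXT	+0.5
PHE	N	+0.5
PHE	CA	-0.5
PHE	C	+0.5
PHE	O	+0.5
PHE	CB	-0.5
PHE	CG	-0.5
PHE	CD1	-0.5
PHE	CD2	-0.5
PHE	CE1	-0.5
PHE	CE2	-0.5
PHE	CZ	-0.5
PHE	OXT	+0.5
PHE	H	+0.5
PHE	H1	+0.5
PHE	H2	+0.5
PHE	H3	+0.5
PHE	HN	+0.5
PHE	HXT	+0.5
TRP	N	+0.5
TRP	CA	-0.5
TRP	C	+0.5
TRP	O	+0.5
TRP	CB	-0.5
TRP	CG	-0.5
TRP	CD1	-0.5
TRP	CD2	-0.5
TRP	NE1	+0.5
TRP	CE2	-0.5
TRP	CE3	-0.5
TRP	CZ2	-0.5
TRP	CZ3	-0.5
TRP	CH2	-0.5
TRP	OXT	+0.5
TRP	H	+0.5
TRP	H1	+0.5
TRP	H2	+0.5
TRP	H3	+0.5
TRP	HN	+0.5
TRP	HXT	+0.5
TRP	HE1	+0.5
MET	N	+0.5
MET	CA	-0.5
MET	C	+0.5
MET	O	+0.5
MET	CB	-0.5
MET	CG	-0.5
MET	SD	-0.5
MET	CE	-0.5
MET	OXT	+0.5
MET	H	+0.5
MET	H1	+0.5
MET	H2	+0.5
MET	H3	+0.5
MET	HN	+0.5
MET	HXT	+0.5
SER	N	+0.5
SER	CA	-0.5
SER	C	+0.5
SER	O	+0.5
SER	CB	-0.5
SER	OG	+0.5
SER	OXT	+0.5
SER	H	+0.5
SER	H1	+0.5
SER	H2	+0.5
SER	H3	+0.5
SER	HN	+0.5
SER	HXT	+0.5
SER	HG	+0.5
THR	N	+0.5
THR	CA	-0.5
THR	C	+0.5
THR	O	+0.5
THR	CB	-0.5
THR	OG1	+0.5
THR	CG2	-0.5
THR	OXT	+0.5
THR	H	+0.5
THR	H1	+0.5
THR	H2	+0.5
THR	H3	+0.5
THR	HN	+0.5
THR	HXT	+0.5
THR	HG1	+0.5
CYS	N	+0.5
CYS	CA	-0.5
CYS	C	+0.5
CYS	O	+0.5
CYS	CB	-0.5
CYS	SG	+0.5
CYS	OXT	+0.5
CYS	H	+0.5
CYS	H1	+0.5
CYS	H2	+0.5
CYS	H3	+0.5
CYS	HN	+0.5
CYS	HXT	+0.5
CYS	HG	+0.5
TYR	N	+0.5
TYR	CA	-0.5
TYR	C	+0.5
TYR	O	+0.5
TYR	CB	-0.5
TYR	CG	-0.5
TYR	CD1	-0.5
TYR	CD2	-0.5
TYR	CE1	-0.5
TYR	CE2	-0.5
TYR	CZ	-0.5
TYR	OH	+0.5
TYR	OXT	+0.5
TYR	H	+0.5
TYR	H1	+0.5
TYR	H2	+0.5
TYR	H3	+0.5
TYR	HN	+0.5
TYR	HXT	+0.5
TYR	HH	+0.5
ASN	N	+0.5
ASN	CA	-0.5
ASN	C	+0.5
ASN	O	+0.5
ASN	CB	-0.5
ASN	CG	+0.5
ASN	OD1	+0.5
ASN	ND2	+0.5
ASN	OXT	+0.5
ASN	H	+0.5
ASN	H1	+0.5
ASN	H2	+0.5
ASN	H3	+0.5
ASN	HN	+0.5
ASN	HXT	+0.5
ASN	HD21	+0.5
ASN	HD22	+0.5
GLN	N	+0.5
GLN	CA	-0.5
GLN	C	+0.5
GLN	O	+0.5
GLN	CB	-0.5
GLN	CG	-0.5
GLN	CD	+0.5
GLN	OE1	+0.5
GLN	NE2	+0.5
GLN	OXT	+0.5
GLN	H	+0.5
GLN	H1	+0.5
GLN	H2	+0.5
GLN	H3	+0.5
GLN	HN	+0.5
GLN	HXT	+0.5
GLN	HE21	+0.5
GLN	HE22	+0.5
ASP	N	+0.5
ASP	CA	-0.5
ASP	C	+0.5
ASP	O	+0.5
ASP	CB	-0.5
ASP	CG	+0.5
ASP	OD1	+0.5
ASP	OD2	+0.5
ASP	OXT	+0.5
ASP	H	+0.5
ASP	H1	+0.5
ASP	H2	+0.5
ASP	H3	+0.5
ASP	HN	+0.5
ASP	HXT	+0.5
GLU	N	+0.5
GLU	CA	-0.5
GLU	C	+0.5
GLU	O	+0.5
GLU	CB	-0.5
GLU	CG	-0.5
GLU	CD	+0.5
GLU	OE1	+0.5
GLU	OE2	+0.5
GLU	OXT	+0.5
GLU	H	+0.5
GLU	H1	+0.5
GLU	H2	+0.5
GLU	H3	+0.5
GLU	HN	+0.5
GLU	HXT	+0.5
LYS	N	+0.5
LYS	CA	-0.5
LYS	C	+0.5
LYS	O	+0.5
LYS	CB	-0.5
LYS	CG	-0.5
LYS	CD	-0.5
LYS	CE	-0.5
LYS	NZ	+0.5
LYS	OXT	+0.5
LYS	H	+0.5
LYS	H1	+0.5
LYS	H2	+0.5
LYS	H3	+0.5
LYS	HN	+0.5
LYS	HXT	+0.5
LYS	HZ1	+0.5
LYS	HZ2	+0.5
LYS	HZ3	+0.5
ARG	N	+0.5
ARG	CA	-0.5
ARG	C	+0.5
ARG	O	+0.5
ARG	CB	-0.5
ARG	CG	-0.5
ARG	CD	-0.5
ARG	NE	+0.5
ARG	CZ	+0.5
ARG	NH1	+0.5
ARG	NH2	+0.5
ARG	OXT	+0.5
ARG	H	+0.5
ARG	H1	+0.5
ARG	H2	+0.5
ARG	H3	+0.5
ARG	HN	+0.5
ARG	HXT	+0.5
ARG	HE	+0.5
ARG	HH11	+0.5
ARG	HH12	+0.5
ARG	HH21	+0.5
ARG	HH22	+0.5
HIS	N	+0.5
HIS	CA	-0.5
HIS	C	+0.5
HIS	O	+0.5
HIS	CB	-0.5
HIS	CG	-0.5
HIS	ND1	+0.5
HIS	CD2	-0.5
HIS	CE1	+0.5
HIS	NE2	+0.5
HIS	OXT	+0.5
HIS	H	+0.5
HIS	H1	+0.5
HIS	H2	+0.5
HIS	H3	+0.5
HIS	HN	+0.5
HIS	HXT	+0.5
HIS	HD1	+0.5
HIS	HE2	+0.5
PHO	C	-0.5
PHI	O	+0.5
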