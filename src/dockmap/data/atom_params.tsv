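# res_name	atom_name	radius	charge	atype
# '*' in res_name matches any standard amino-acid residue.
# Backbone template sums to zero; sidechain entries are balanced within each residue.
*	N	1.8	-0.30	N_don
*	CA	1.9	0.30	C_aliph
*	C	1.9	0.45	C_aliph
*	O	1.7	-0.45	O_acc
*	OXT	1.7	0.00	O_acc
*	CB	1.9	0.00	C_aliph
GLY	CA	1.9	0.30	C_aliph
ALA	CB	1.9	0.00	C_aliph
SER	CB	1.9	0.25	C_aliph
SER	OG	1.7	-0.25	O_acc
THR	CB	1.9	0.25	C_aliph
THR	OG1	1.7	-0.25	O_acc
THR	CG2	1.9	0.00	C_aliph
CYS	CB	1.9	0.10	C_aliph
CYS	SG	2.0	-0.10	S
VAL	CG1	1.9	0.00	C_aliph
VAL	CG2	1.9	0.00	C_aliph
LEU	CG	1.9	0.00	C_aliph
LEU	CD1	1.9	0.00	C_aliph
LEU	CD2	1.9	0.00	C_aliph
ILE	CG1	1.9	0.00	C_aliph
ILE	CG2	1.9	0.00	C_aliph
ILE	CD1	1.9	0.00	C_aliph
MET	CG	1.9	0.05	C_aliph
MET	SD	2.0	-0.10	S
MET	CE	1.9	0.05	C_aliph
PRO	CG	1.9	0.00	C_aliph
PRO	CD	1.9	0.00	C_aliph
PHE	CG	1.9	0.00	C_arom
PHE	CD1	1.9	0.00	C_arom
PHE	CD2	1.9	0.00	C_arom
PHE	CE1	1.9	0.00	C_arom
PHE	CE2	1.9	0.00	C_arom
PHE	CZ	1.9	0.00	C_arom
TYR	CG	1.9	0.00	C_arom
TYR	CD1	1.9	0.00	C_arom
TYR	CD2	1.9	0.00	C_arom
TYR	CE1	1.9	0.00	C_arom
TYR	CE2	1.9	0.00	C_arom
TYR	CZ	1.9	0.25	C_arom
TYR	OH	1.7	-0.25	O_acc
TRP	CG	1.9	0.00	C_arom
TRP	CD1	1.9	0.10	C_arom
TRP	CD2	1.9	0.00	C_arom
TRP	NE1	1.8	-0.10	N_don
TRP	CE2	1.9	0.00	C_arom
TRP	CE3	1.9	0.00	C_arom
TRP	CZ2	1.9	0.00	C_arom
TRP	CZ3	1.9	0.00	C_arom
TRP	CH2	1.9	0.00	C_arom
ASP	CG	1.9	0.50	C_aliph
ASP	OD1	1.7	-0.25	O_acc
ASP	OD2	1.7	-0.25	O_acc
GLU	CG	1.9	0.00	C_aliph
GLU	CD	1.9	0.50	C_aliph
GLU	OE1	1.7	-0.25	O_acc
GLU	OE2	1.7	-0.25	O_acc
ASN	CG	1.9	0.50	C_aliph
ASN	OD1	1.7	-0.30	O_acc
ASN	ND2	1.8	-0.20	N_don
GLN	CG	1.9	0.00	C_aliph
GLN	CD	1.9	0.50	C_aliph
GLN	OE1	1.7	-0.30	O_acc
GLN	NE2	1.8	-0.20	N_don
HIS	CG	1.9	0.10	C_arom
HIS	ND1	1.8	-0.20	N_don
HIS	CD2	1.9	0.10	C_arom
HIS	CE1	1.9	0.20	C_arom
HIS	NE2	1.8	-0.20	N_don
LYS	CG	1.9	0.00	C_aliph
LYS	CD	1.9	0.00	C_aliph
LYS	CE	1.9	0.25	C_aliph
LYS	NZ	1.8	-0.25	N_don
ARG	CG	1.9	0.00	C_aliph
ARG	CD	1.9	0.10	C_aliph
ARG	NE	1.8	-0.20	N_don
ARG	CZ	1.9	0.50	C_aliph
ARG	NH1	1.8	-0.20	N_don
ARG	NH2	1.8	-0.20	N_don
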