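# Hydrogen-bond acceptor heavy atoms per residue template.
# residue_name	atom_name
ALA	O
ARG	O
ASN	O
ASN	OD1
ASP	O
ASP	OD1
ASP	OD2
CYS	O
CYS	SG
GLN	O
GLN	OE1
GLU	O
GLU	OE1
GLU	OE2
GLY	O
HIS	O
HIS	ND1
HIS	NE2
ILE	O
LEU	O
LYS	O
MET	O
MET	SD
PHE	O
PRO	O
SER	O
SER	OG
THR	O
THR	OG1
TRP	O
TYR	O
TYR	OH
VAL	O
A	OP1
A	OP2
A	O1P
A	O2P
A	O5'
A	O3'
A	O4'
A	O2'
A	N1
A	N3
A	N7
C	OP1
C	OP2
C	O1P
C	O2P
C	O5'
C	O3'
C	O4'
C	O2'
C	O2
C	N3
G	OP1
G	OP2
G	O1P
G	O2P
G	O5'
G	O3'
G	O4'
G	O2'
G	O6
G	N3
G	N7
U	OP1
U	OP2
U	O1P
U	O2P
U	O5'
U	O3'
U	O4'
U	O2'
U	O2
U	O4
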