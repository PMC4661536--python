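# Hydrogen-bond donor heavy atoms per residue template.
# residue_name	atom_name
# Backbone amide N applies to all amino acids (listed per residue for completeness).
ALA	N
ARG	N
ARG	NE
ARG	NH1
ARG	NH2
ASN	N
ASN	ND2
ASP	N
CYS	N
CYS	SG
GLN	N
GLN	NE2
GLU	N
GLY	N
HIS	N
HIS	ND1
HIS	NE2
ILE	N
LEU	N
LYS	N
LYS	NZ
MET	N
PHE	N
SER	N
SER	OG
THR	N
THR	OG1
TRP	N
TRP	NE1
TYR	N
TYR	OH
VAL	N
A	O2'
A	N6
C	O2'
C	N4
G	O2'
G	N1
G	N2
U	O2'
U	N3
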