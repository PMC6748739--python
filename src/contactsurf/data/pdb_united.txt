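# contactsurf radii table, version 1
# name: pdb-united
# United-atom van der Waals radii (Angstrom) for PDB input: hydrogens are
# implicit in heavy-atom radii (Chothia-1976/NACCESS-style values).
# Line formats:
#   <RESNAME> <ATOMNAME> <radius>   residue-specific entry
#   * <ATOMNAME> <radius>           any-residue entry (backbone, nucleic acids)
#   ELEM <ELEMENT> <radius>         element-level fallback
#   FALLBACK <radius>               last resort
#
# protein backbone
* N 1.65
* CA 1.87
* C 1.76
* O 1.40
* OXT 1.40
# nucleic acid sugar-phosphate backbone
* P 1.90
* OP1 1.40
* OP2 1.40
* OP3 1.40
* O1P 1.40
* O2P 1.40
* O5' 1.40
* C5' 1.87
* C4' 1.87
* O4' 1.40
* C3' 1.87
* O3' 1.40
* C2' 1.87
* O2' 1.40
* C1' 1.87
# nucleobase atoms (names do not collide with amino-acid side chains)
* N1 1.65
* C2 1.76
* N3 1.65
* C4 1.76
* C5 1.76
* C6 1.76
* N7 1.65
* C8 1.76
* N9 1.65
* O2 1.40
* O4 1.40
* O6 1.40
* N2 1.65
* N4 1.65
* N6 1.65
* C7 1.87
* C5M 1.87
# amino-acid side chains: tetrahedral C 1.87, trigonal/aromatic C 1.76,
# N 1.65 (charged NZ 1.50), O 1.40, S 1.85
ALA CB 1.87
ARG CB 1.87
ARG CG 1.87
ARG CD 1.87
ARG NE 1.65
ARG CZ 1.76
ARG NH1 1.65
ARG NH2 1.65
ASN CB 1.87
ASN CG 1.76
ASN OD1 1.40
ASN ND2 1.65
ASP CB 1.87
ASP CG 1.76
ASP OD1 1.40
ASP OD2 1.40
CYS CB 1.87
CYS SG 1.85
GLN CB 1.87
GLN CG 1.87
GLN CD 1.76
GLN OE1 1.40
GLN NE2 1.65
GLU CB 1.87
GLU CG 1.87
GLU CD 1.76
GLU OE1 1.40
GLU OE2 1.40
HIS CB 1.87
HIS CG 1.76
HIS ND1 1.65
HIS CD2 1.76
HIS CE1 1.76
HIS NE2 1.65
ILE CB 1.87
ILE CG1 1.87
ILE CG2 1.87
ILE CD1 1.87
LEU CB 1.87
LEU CG 1.87
LEU CD1 1.87
LEU CD2 1.87
LYS CB 1.87
LYS CG 1.87
LYS CD 1.87
LYS CE 1.87
LYS NZ 1.50
MET CB 1.87
MET CG 1.87
MET SD 1.85
MET CE 1.87
MSE CB 1.87
MSE CG 1.87
MSE SE 1.90
MSE CE 1.87
PHE CB 1.87
PHE CG 1.76
PHE CD1 1.76
PHE CD2 1.76
PHE CE1 1.76
PHE CE2 1.76
PHE CZ 1.76
PRO CB 1.87
PRO CG 1.87
PRO CD 1.87
SER CB 1.87
SER OG 1.40
THR CB 1.87
THR OG1 1.40
THR CG2 1.87
TRP CB 1.87
TRP CG 1.76
TRP CD1 1.76
TRP CD2 1.76
TRP NE1 1.65
TRP CE2 1.76
TRP CE3 1.76
TRP CZ2 1.76
TRP CZ3 1.76
TRP CH2 1.76
TYR CB 1.87
TYR CG 1.76
TYR CD1 1.76
TYR CD2 1.76
TYR CE1 1.76
TYR CE2 1.76
TYR CZ 1.76
TYR OH 1.40
VAL CB 1.87
VAL CG1 1.87
VAL CG2 1.87
# common monoatomic ions (residue name equals atom name)
NA NA 2.27
K K 2.75
MG MG 1.73
CA CA 2.31
ZN ZN 1.39
CL CL 1.75
# element-level fallback
ELEM C 1.80
ELEM N 1.65
ELEM O 1.40
ELEM S 1.85
ELEM P 1.90
ELEM H 1.00
ELEM D 1.00
ELEM F 1.47
ELEM CL 1.75
ELEM BR 1.85
ELEM I 1.98
ELEM SE 1.90
FALLBACK 1.80
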