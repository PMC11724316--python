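# ionshell role templates, version 1
# residue_name	atom_name	category
#
# Nucleotide first-shell donor/acceptor categories:
#   Oph  anionic phosphate oxygens OP1/OP2
#   Or   ribose / phosphodiester bridging oxygens O2'/O3'/O4'/O5'
#   Ob   nucleobase carbonyl oxygens O2/O4/O6
#   Nb   non-protonated nucleobase ring nitrogens (per-base template below;
#        (G)N1, (U/T)N3, glycosidic N9/N1 and amino nitrogens are excluded)
# Protein categories:
#   Obb  backbone carbonyl oxygen (incl. OXT)
#   Ocoo Asp/Glu carboxylate oxygens
#   Ocno Asn/Gln side-chain carbonyl oxygens
#   OHprot Ser/Thr/Tyr hydroxyl oxygens
#   NHis non-protonated His ND1/NE2
# Waters (HOH/WAT/DOD -> Ow) and metals (MG/K/NA/ZN -> metal) are matched by
# rule in code, not listed here. Everything unmatched degrades to "other".
A	OP1	Oph
A	OP2	Oph
A	O2'	Or
A	O3'	Or
A	O4'	Or
A	O5'	Or
A	N1	Nb
A	N3	Nb
A	N7	Nb
G	OP1	Oph
G	OP2	Oph
G	O2'	Or
G	O3'	Or
G	O4'	Or
G	O5'	Or
G	O6	Ob
G	N3	Nb
G	N7	Nb
C	OP1	Oph
C	OP2	Oph
C	O2'	Or
C	O3'	Or
C	O4'	Or
C	O5'	Or
C	O2	Ob
C	N3	Nb
U	OP1	Oph
U	OP2	Oph
U	O2'	Or
U	O3'	Or
U	O4'	Or
U	O5'	Or
U	O2	Ob
U	O4	Ob
DA	OP1	Oph
DA	OP2	Oph
DA	O3'	Or
DA	O4'	Or
DA	O5'	Or
DA	N1	Nb
DA	N3	Nb
DA	N7	Nb
DG	OP1	Oph
DG	OP2	Oph
DG	O3'	Or
DG	O4'	Or
DG	O5'	Or
DG	O6	Ob
DG	N3	Nb
DG	N7	Nb
DC	OP1	Oph
DC	OP2	Oph
DC	O3'	Or
DC	O4'	Or
DC	O5'	Or
DC	O2	Ob
DC	N3	Nb
DT	OP1	Oph
DT	OP2	Oph
DT	O3'	Or
DT	O4'	Or
DT	O5'	Or
DT	O2	Ob
DT	O4	Ob
ALA	O	Obb
ALA	OXT	Obb
ARG	O	Obb
ARG	OXT	Obb
ASN	O	Obb
ASN	OXT	Obb
ASN	OD1	Ocno
ASP	O	Obb
ASP	OXT	Obb
ASP	OD1	Ocoo
ASP	OD2	Ocoo
CYS	O	Obb
CYS	OXT	Obb
GLN	O	Obb
GLN	OXT	Obb
GLN	OE1	Ocno
GLU	O	Obb
GLU	OXT	Obb
GLU	OE1	Ocoo
GLU	OE2	Ocoo
GLY	O	Obb
GLY	OXT	Obb
HIS	O	Obb
HIS	OXT	Obb
HIS	ND1	NHis
HIS	NE2	NHis
ILE	O	Obb
ILE	OXT	Obb
LEU	O	Obb
LEU	OXT	Obb
LYS	O	Obb
LYS	OXT	Obb
MET	O	Obb
MET	OXT	Obb
PHE	O	Obb
PHE	OXT	Obb
PRO	O	Obb
PRO	OXT	Obb
SER	O	Obb
SER	OXT	Obb
SER	OG	OHprot
THR	O	Obb
THR	OXT	Obb
THR	OG1	OHprot
TRP	O	Obb
TRP	OXT	Obb
TYR	O	Obb
TYR	OXT	Obb
TYR	OH	OHprot
VAL	O	Obb
VAL	OXT	Obb
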